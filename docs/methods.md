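# Methods

## Contact scoring model

A *contact* is an inter-chain residue pair of one predicted model with at
least one non-hydrogen atom pair strictly closer than the contact cutoff.
Hydrogens are excluded by element, never by atom name. All comparators in
the scoring chain are strict and follow the conventional screen settings
verbatim: contacts at < 8 Å; residues with pLDDT < 50 excluded (a residue
at exactly 50 is kept); residue pairs with pAE > 15 Å excluded (exactly
15 kept); confident interactions at *average models* > 0.5 (exactly 0.5
is not confident).

pAE is directional. For the pair filter and for interface-pAE averaging
the two directions are combined by their arithmetic mean by default;
`max` (conservative) and `min` (permissive) are selectable via
`ScoreConfig.pae_combine` and echoed into every output table. Interface
pAE averages over contact *instances* pooled across the five models — a
pair contributes once per model containing it — because the pooled
reading weights recurrent, well-supported pairs; a union-unique variant
(`pae_pool="union"`) is provided. With no surviving contacts the
interface pAE is undefined and reported as a missing value, never as 0.

Contacts are matched across models by their `(chain_id, residue_index)`
pairs; the five models of one target share residue numbering by
construction, so no alignment step is needed. The *average models* score
over the cross-model union U is `(Σ_c m(c) / |U|) / n` with `m(c)` the
model count of contact c; an empty union scores 0, otherwise the score
lies in [1/n, 1]. The reported ipTM is the top-ranked model's value,
read from the confidence file and never recomputed.

The pAE matrix is addressed by the concatenated residue index in
model/chain order. That index is always derived on the fly from the
chain layout; only the per-chain 1-based residue numbering is stored.

## Structure confidence I/O

Per-residue pLDDT is read from the PDB B-factor column. The value on the
first atom of each residue is used, and all atoms of a residue must agree
within 0.01 — predicted-structure writers emit one value per residue, so
disagreement indicates corruption and raises rather than averaging.
mmCIF input uses the same per-atom isotropic-B channel. pAE matrices are
never symmetrized, reordered, or clipped by I/O.

## Domain mapping and percent identity

Domain windows are defined as residue intervals on a reference sequence
(the human ortholog in the motivating application; boundaries are user
configuration, not computed). The reference residues select an inclusive
alignment-column span; the mapped window on a target runs from its first
to its last residue inside that span, so insertions the target carries
within the window count toward its length — deliberate, because
insertions in the region are themselves evidence of degeneracy. A target
that is all-gap over the span has the domain *absent*.

Percent identity over a window is matches divided by the number of
reference non-gap positions in the window's columns, × 100. The
denominator is a property of the reference only, so target gaps lower
identity but never shrink the denominator. Comparison is
case-insensitive; an undetermined residue `X` never matches. A window
with zero reference positions cannot arise from a residue-indexed window
and is reported as missing if forced.

## Conservation calls

Helices are assigned from backbone dihedrals: a residue is helical when
φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°]; maximal runs of ≥ `min_helix_len`
(default 6) residues form segments. A dihedral rule was chosen over
DSSP-style hydrogen-bond assignment because it is deterministic,
dependency-free, and exact on ideal-geometry fixtures; on real AlphaFold
models it is a documented proxy for visual inspection and the two need
not coincide at helix termini.

A three-helix binding-domain window is **conserved** iff all three
helices are detected and the mapped window length does not exceed the
reference length by more than `insertion_tolerance` (default 0.30 — the
motif tolerates short indels, but a window inflated by a third or more
indicates an insertion disrupting the fold). Fewer helices, or an
inflated window, give **non_conserved**; a window with no mapped residues
is **absent**.

The tether call requires only `tether_min_len` residues (default 12,
enough backbone to form a short loop-helix element) in the mapped window,
with secondary structure explicitly ignored: the element is intrinsically
flexible and typically sits below the pLDDT ≥ 70 backbone-reliability
threshold, so demanding a predicted helix would reject real tethers.
Both thresholds are configuration, reported in every output row. The
pLDDT ≥ 70 reliability threshold is inclusive.

Superposition is least-squares (Kabsch, proper rotations only) over
paired Cα atoms, requiring ≥ 3 pairs. A useful exactness check: for a
one-atom displacement of d with the displaced atom at the centroid, the
optimal rotation is the identity and the minimal RMSD is d·√(n−1)/n —
note the n−1: re-optimizing the translation absorbs 1/n of the
displacement, so a single displaced atom can never be the sole residual
of an optimal fit.

## Ortholog screen

Hits below a per-subunit identity floor are discarded as false positives
(defaults: 50% for MCM2, 30% for ORC subunits — misassigned-subunit and
CDC6-like hits sit below 30% while true orthologs sit well above; floors
are overridable per taxon group because the separation varies across
clades). Among surviving hits per (species, subunit) the representative
is the highest query coverage, tie-broken by higher identity then
lexicographic accession for determinism. A taxon group is excluded iff
two or more of the six ORC subunits are absent across all of its species;
one missing subunit is the biological signal, not a data-quality flag. A
group is ORC6-negative iff no species has ORC6 while ORC1–5 are each
present somewhere in the group. Sequence QC rejects sequences with
undetermined residues, partial ORC3 truncated within the insertion
domain (partials outside it only pass in data-poor groups, < 10
species), and partial MCM2 missing the N-terminal interaction region.
Representative subsetting is greedy round-robin over class/order labels,
deterministic under sorted visiting order.

## Statistics

Group comparisons use the two-tailed Mann–Whitney U test with midrank
ties. When the smaller group has ≤ 8 values the exact permutation
distribution is computed by dynamic programming over doubled midranks
(doubling makes midranks integral); two-tailed p is twice the smaller
tail, capped at 1. Larger samples use the normal approximation with tie
correction and a 0.5 continuity correction. p values are reported to
four decimal places. Missing values (an interface pAE that could not be
calculated) are dropped listwise per metric, never imputed. Normality
screening, where wanted, is delegated to standard library routines
(e.g. `scipy.stats.shapiro`) and is not part of this package. No
multiple-testing correction is applied.

## Synthetic fixtures: what they emulate, and what they do not

Fixture geometry is constructed, not simulated. Chains lie on rails with
20 Å between neighbouring residue centres and 1000 Å between chains; a
designated contact is realised by placing the partner residue 4–6 Å away
(seeded jitter), which makes the placed pairs exactly the pairs under
the 8 Å cutoff and keeps everything else beyond 10 Å. Ground truth is
therefore analytic: with s pairs shared by all n models and u singleton
pairs, the filtered score is (n·s + u)/(n·(s + u)) exactly. Each residue
of a designated pair may appear in only one pair (a residue cannot
occupy two contact sites, and a sub-50 decoy residue would silently
erase a true contact); violating specs raise an infeasible-geometry
error. One global seed derives per-model seeds (seed + model ordinal),
so files regenerate byte-identically.

Domain fixtures build real backbones from internal coordinates (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; ideal-helix φ = −57°, ψ = −47°;
loops at φ = −140°, ψ = 145°; ω = 180°), so the helix detector runs on
actual geometry rather than labels. Mock alignments carry contiguous gap
blocks over ≥ 50% of the domain columns in degenerate rows; mock hit
tables draw true orthologs at 50–90% identity and false positives below
30%.

What the fixtures do **not** emulate: realistic side-chain packing or
Ramachandran spread, pLDDT/pAE correlation structure, partially shared
interfaces with near-cutoff distances, alignment errors, or paralog
confusion beyond the identity-band caricature. Passing tests therefore
demonstrate the correctness of the rules and arithmetic on inputs with
known truth — not the biological accuracy of any threshold on real
predictions, which at full scale depends on GPU-generated model sets
that cannot be regenerated here.

## Pipeline and problem sizes

The demo cohort is 12 species in three groups of four: conserved BD with
fully shared interfaces; degenerate BD (one helix missing, ORC6 absent)
with five disjoint single-model contacts; and conserved BD with a
3-residue tether window and shared interfaces. Multimer fixtures use
46 + 30 residue chains with six interface pairs; domain fixtures use
three 10-residue helices with 4-residue loops. These sizes keep a full
run in the seconds range while exercising every rule; all stage TSVs
echo their thresholds, and the manifest records seed, config hash, and
per-stage row counts. Stages are re-run rather than cached: with
byte-identical determinism under a fixed seed (asserted in tests),
caching would add invalidation complexity without observable benefit at
these sizes.

## Known limitations

* The conserved/non-conserved classifier is an automated proxy for what
  is, in practice, expert visual inspection; boundary cases (distorted
  termini, marginal insertions) are decided by the configured thresholds.
* Identity floors and domain windows are configuration; the package
  ships sensible defaults, not curated per-clade values.
* `score` consumes exactly five models per target; screens with other
  model counts need `ScoreConfig.n_models` adjusted consistently.
* Interface pAE pooling ("instances" vs "union") changes the reported
  value when contact sets differ across models; the choice is logged in
  the config echo of every output.
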