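# Methods

This note records the models implemented by `collagen-gpo`, the
assumptions behind them, the defaults and why they were chosen, and the
limits of what a green test establishes. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Conservation scoring

**Model.** A pre-aligned ortholog set of one collagen α-chain (one
representative sequence per species; the package never aligns) is scored
per triplet site: `p_gpo` is the fraction of sequences whose three
alignment columns read exactly G, P and a Y-match with no gap. A site is
*conserved* when `p_gpo ≥ threshold` (closed bound; default 0.75, so a
site at exactly 75% is conserved).

**Hydroxylation rule.** Sequence databases encode hydroxyproline as
plain `P`, so by default a Y-position `P` counts as Hyp (`GPP` ⇒ GPO);
`hydroxylated_y=False` requires a literal `O`. The unknown residue `X`
never matches any triplet test.

**Consensus and register.** The consensus takes the modal non-gap
residue of each column; ties break alphabetically (deterministic and
reproducible — `O` before `P`), and a column is dropped only when gaps
strictly outnumber every residue (on a gap/residue tie the residue
wins). The G-X-Y register is found once on the consensus — the triple
helix has one shared register — by choosing the offset in {0, 1, 2}
maximising Gly at triplet position 1 (ties to the smallest offset); if
the best offset still leaves Gly below 50% of those positions the
sequence has no credible register and an error is raised. Sequences
contribute to `p_gpo` only when ungapped across the whole triplet: a
gapped triplet is not a GPO occurrence.

## Fibril layout and GPO bands

**Model.** Molecules in the fibril are staggered by one D period
(default 234 residues — the standard axial stagger; configurable), with
five molecules per repeat (`n_molecules=5`) and the three chains of a
molecule staggered by one residue. Axial coordinates are integers in
residue units, 0-based at molecule 1 / leading chain / residue 1, with
half-open ranges throughout. An axial position is in the *overlap* zone
iff every molecule has a residue there, else *hole*; because the
molecule (≈1014 residues) is shorter than 5·D, the fifth segment D5 is
short and creates the hole zone.

**Bands.** The banding of GPO sites has no quantitative definition in
the source imagery, so the detector is an explicit decision: every
sliding window of `window_w = 9` residues (three triplets) containing at
least `min_count = 4` conserved-GPO residues qualifies; overlapping
qualifying windows merge into maximal disjoint intervals, trimmed to
occupied positions. Merged bands may exceed `window_w`; two clusters
more than a window apart always separate. Both parameters are exposed.
The same detector applied to a single chain in helix coordinates defines
the in-band/isolated split used by the mutation stage (one isolated site
contributes 3 residues < `min_count`, so ≥ 2 nearby sites are needed to
form a band).

**Zone of a locus.** A zone belongs to an axial position, not to a helix
locus; for per-locus tabulations (chain-symmetry by zone) each locus is
assigned the zone of its Gly in the central molecule, which sits in the
fully tiled region of the modelled segment.

**Binding sites.** Binding-site coordinates are user input (TSV or
constructed annotations). The flank call uses the distance from the site
interval to the nearest band's centroid (0 when the intervals overlap);
sides are N-terminal / C-terminal / overlapping relative to that
centroid.

## Mutation overlap

Variant tables mimic a ClinVar export; filtering keeps rows whose
molecular consequence contains "missense", whose variation type is
"single nucleotide" and with at least one review star, then collapses
duplicates of the same (chain, position, ref, alt). A mutation overlaps
iff its 1-based helix position (counted from the first Gly of the
triple-helical domain; any propeptide offset is the data provider's
concern) equals the G, P or O position of a conserved triplet.
Percentages are reported half-up at one decimal:
`pct_overlapping = 100·n_overlapping/n_mutations` and
`pct_helix = 100·3·n_conserved/helix_length`. Positions beyond the
consensus are flagged, logged and excluded from the denominator; an
empty mutation set reports the percentage as not applicable rather
than 0.

## Triple-helix geometry

**Dihedrals.** Signed torsions follow the IUPAC convention, wrapped to
(−180°, 180°]; φ = C(i−1)-N-CA-C, ψ = N-CA-C-N(i+1); terminal residues
carry `None` for the missing angle.

**Pucker.** Endo/exo is operationalised as the signed displacement of Cγ
from the plane through N, CA and CD, positive toward the residue's
carbonyl carbon: endo ⇔ displacement > +δ_min, exo ⇔ < −δ_min, planar
otherwise (δ_min = 0.1 Å). A 5-atom least-squares mean-plane classifier
(Cremer–Pople in spirit) lives in the test suite as an independent
cross-check of the *side*; its displacement magnitudes are smaller
because the mean plane tilts toward Cγ, so only the sign is compared.

**Builder.** Ideal chains are built by natural-extension (NeRF) internal
coordinates at canonical PPII dihedrals (−75°, 150°), trans peptide
bonds and Engh–Huber-like bond geometry. Proline CB/CD/CG start from the
chemical-component-dictionary proline template; CB is rotated about the
N–CA axis to a small opposite-side displacement and CG about the Cβ–Cδ
axis until its plane displacement equals the designed value (±0.45 Å by
default) — both rotations are isometries, so ring bond lengths stay
ideal, and the solution nearest the template is taken. Hydroxyproline
adds OD1 on Cγ pointing out of the ring and always builds *exo*, its
strongly preferred state. The three chains are identical copies offset
by one stagger rise (2.9 Å) axially and 12 Å laterally: these models
carry register, connectivity and pucker for testing, **not** real
triple-helix packing, and the lateral spacing guarantees the
distance-based bond graph (cutoff 1.9 Å) never sees inter-chain
contacts.

**Perturbation sampling.** A perturbation spec lists rotation groups as
atom pairs joined by a covalent path (the standard set for one X-position
imino residue: its Cβ–Cδ ring tip, the Cα–Cα peptide axis to the Y
residue, the Y residue's own axis, and the trailing Cα–Cα axis — jointly
sampling φ/ψ of X and Y, the flanking Gly dihedrals and both ring
puckers). Each sampled conformer rotates *every* group by an independent
angle uniform in (−A, +A) from a seeded generator; the source procedure
describes one pair per perturbation but motivates the group set as
jointly covering the dihedral space, and joint rotation explores it
uniformly with the identity at A → 0 either way. Atoms strictly between
the pair plus their side branches rotate rigidly; everything else is
untouched. Neither the amplitude bound nor the distribution of the
original 10 000 perturbations over groups is stated anywhere, so both
are exposed parameters (defaults A = 25°, n = 200 in `run-all`, chosen
to finish in seconds while accepting a non-trivial fraction).

**No force field.** There is no energy minimisation: geometric
perturbation plus window filtering replaces it. Conformers are accepted
iff every perturbed residue lies in the closed window φ ∈ [−90°, −50°],
ψ ∈ [130°, 170°]. Consequently literal counts of energy minima (which
are force-field-dependent) are out of scope by design; the unique-count
analogue here is greedy leader clustering in (φ, ψ, pucker) space:
conformers join a cluster iff they share the pucker combination and
every angle differs circularly by ≤ 5° from the cluster leader. Greedy
leaders and all-pairs tolerance-graph components agree when clusters are
separated by more than the tolerance (the configuration the tests
construct); for chained borderline cases greedy may split what a
transitive closure would join — an accepted property of leader
clustering.

**Backbone span.** Extension/compression is measured as the distance
from the first N to the last C of a chain built (or measured) at given
(φ, ψ); the fully extended backbone near (180°, 180°) is longer than the
compressed coil at (−20°, 120°), and span grows approximately linearly
with residue count at fixed dihedrals.

## Two-state NMR model

Fast exchange is assumed unconditionally; no lineshape or relaxation
physics is modelled. Default endpoints are δ_endo = 23.8 ppm and
δ_exo = 25.7 ppm (configurable); `endo_fraction` inverts the
population-weighted average, clamping values up to 0.2 ppm outside the
interval into [0, 1] with a warning flag and raising beyond that (a
wrong assignment, not a population). The *proline effect* reduces Cα,
Cβ and C′ of residues preceding an imino acid by 1.5 ppm by default (the
midpoint of the literature 1–2 ppm range; values outside warn but
apply); Cγ and Cδ are never adjusted, and a table flag guards against
double application. DQ-SQ peaks place each bonded carbon pair at
(SQ, DQ = SQ₁+SQ₂) along the C′-Cα-Cβ-Cγ-Cδ walk; the 2D simulator sums
unit-integral Gaussians so integrated intensities are proportional to
peak weights. Intensity ratios report raw and 1-decimal values; with
233 GPY and 103 GPO triplets per triple helix the expected GPY:GPO ratio
is 2.26 ≈ 2.3.

A known tension, noted and left unresolved: prior work places the
(GPO)₁₁ peptide near a 50:50 endo/exo equilibrium while its Cγ shift of
25.3 ppm maps to p_endo ≈ 0.21 under these linear endpoints; no test
asserts a population for 25.3 ppm.

## Synthetic data: what it emulates and what it does not

Each generator draws from a deterministic sub-stream of one master seed
(`default_rng([seed, stream, crc32(label)])`), so outputs are
byte-identical under a seed and adding an artifact never shifts another.
Every artifact comes with a truth table (TSV, `# seed=` header).

* **Ortholog sets** (defaults: 50 species, 338 triplets ≈ the 1014-residue
  triple-helical domain). The α1-like template carries 43 designed GPO
  sites (33 at retention 0.95, 10 at 0.50, ending in a (GPO)₅ run), the
  α2-like 33 sites (20 high, 13 low, (GPO)₄ run) — mirroring the
  reported 43/33 consensus and 33/20 conserved counts; the retention
  probabilities themselves are generator choices, as no per-site values
  are published. Non-GPO sites draw X/Y from common collagen residues;
  per-species substitution noise is 2% per residue and whole triplets
  delete (gap) at 1% — collagen indels occur in triplet units, which
  keeps the register intact. The truth table records *realised* per-site
  GPO counts tallied at generation time, so profile recovery is exact by
  construction. Not emulated: phylogenetic correlation between species,
  rate heterogeneity, isoforms, alignment errors — a green recovery test
  establishes correct counting, not robustness to misalignment.
* **Mutation tables** plant composition directly (α1 story: 95 unique
  retained of which 10 on conserved GPO positions, plus 15 filter-failing
  rows and 10 duplicates; α2: 110/9). Positions, substitutions, star
  counts and conditions are random; no codon structure or mutational
  spectrum is modelled.
* **Helices**: see builder above. Pucker designs `all-endo`, `all-exo`,
  `alternating`, `random`; truth lists every ring state.
* **Shift tables** (defaults: 200 sites, noise σ = 0.05 ppm): Cγ =
  `average_shift(p_endo) + N(0, σ)` with planted p_endo uniform in
  [0.2, 0.8] — kept away from 0/1 so clamping cannot bias recovery — and
  base values for C′/Cα/Cβ/Cδ with the proline effect pre-applied to GPO
  sites (the table is flagged accordingly). The Monte-Carlo recovery
  check compares the mean recovered population to the planted mean
  within 3·σ_p/√n (σ_p = σ/(δ_exo−δ_endo)): a per-site "all within 3σ"
  reading fails ≈ 42% of the time for 200 Gaussian sites and is not a
  calibrated criterion. Per-site scatter is separately checked against
  σ_p.

## Numerical conventions and edge cases

Angles in degrees, wrapped to (−180°, 180°]; coordinates in Å; shifts in
ppm. Percentages round half-up to one decimal (display convention).
Closed intervals for the conservation threshold and the φ/ψ window.
Degenerate dihedrals (collinear central atoms) raise rather than return
a value; a ring within δ_min of planar classifies as `planar`, not an
error. PDB round trips preserve coordinates to the format's 3-decimal
precision. All randomness flows from explicit seeds recorded in output
headers.

## Known limitations

No force-field energetics, transition states or kinetics; no real
supramolecular packing (the D-period model is 1-D axial); telopeptides
are excluded (triple-helical domain only); no survivor-bias correction
in the mutation analysis; binding-site coordinates must be supplied by
the user; the NMR model is shift algebra only.
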