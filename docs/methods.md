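# Methods

This note documents the models, conventions and numerical choices behind
`faakit`, in the order the pipeline runs them, and states what the synthetic
generators do and do not emulate.

## Curation

A candidate condensation-domain sequence enters the comparative analysis only
when three independent pieces of evidence agree:

| rule | statistic | default | sense |
|---|---|---|---|
| length window | domain length (residues) | 300–520 | inclusive at both ends |
| model coverage | `(model_to − model_from + 1) / model_length` | ≥ 0.70 | inclusive |
| boundary overlap | `|envelope ∩ annotation| / |annotation|` | ≥ 0.90 | inclusive |

All thresholds are inclusive (a hit at exactly the threshold passes);
coverage is measured on profile-HMM *model* coordinates, the standard reading
of "model coverage". The overlap denominator is the annotated span, so the
statistic reads "how much of the annotated domain does the hit recover".
When a sequence has several domain hits, the one with the highest model
coverage decides (ties: larger overlap, then first occurrence); multiple
hits per sequence are rare in practice and the choice is recorded in the
audit table either way. Profile-HMM search itself is out of scope: hits are
consumed from hmmsearch per-domain tables or an equivalent 6-column TSV, and
the package's own computation is the filtering. Non-canonical residues
(X/B/Z/U) are tolerated at curation; their handling is fixed at profiling.

## Column profiling and consensus cores

For an aligned family with `n` rows, column `j` has

* occupancy `occ_j = n_nongap / n`,
* conservation `cons_j = n_top / n_nongap` (undefined for all-gap columns).

The conservation denominator is the non-gap count: occupancy and conservation
are deliberately independent axes, one measuring how often the column is
present at all, the other how uniform it is when present. X/B/Z/U count
toward occupancy (they are residues, not gaps) but can never be the top
residue, because a consensus must be a canonical amino acid to be alignable
and mappable downstream.

Columns with `occ_j < 0.70` are dropped — a strict lower cut, so a column at
exactly 0.70 survives. The consensus core takes the most frequent canonical
residue of each surviving column, with ties broken lexicographically by
one-letter code (deterministic and documented; any fixed rule would do, and
ties essentially only occur in small or degenerate families). Landmarks
require `cons_j ≥ 0.85` and `occ_j ≥ 0.80`, both inclusive.

Every trimmed or derived object carries a `column_map` back to original
1-based alignment columns; no coordinates are ever re-based silently.

Motif tables: the catalytic motif is located by a single-anchor regex scan of
the consensus (`[DH]H...D.` by default). Zero or multiple matches are an
error that forces explicit anchor columns — silent disambiguation would be
worse than failing. Slot frequencies are computed over non-gap cells; the
output metadata records this convention since percentages over all rows
would differ in gappy families.

## Shared grid and SDP identification

Consensus cores are compared pairwise: one target subtype against one
comparison subtype. The two cores are globally aligned with an affine-gap
Needleman–Wunsch (Gotoh three-state) under BLOSUM62 with gap open 10 and
extend 1, a gap run of length L costing `10 + 1·L`. A dedicated two-sequence
aligner was chosen over calling an external multiple aligner because the
inputs are two ungapped, homologous cores: the optimal pairwise alignment is
well-defined, dependency-free, and exactly reproducible (traceback ties
resolve diagonal > up > left). The aligner is verified against exhaustive
alignment enumeration at small lengths and against an independent aligner
implementation at realistic lengths.

Each grid position carries both subtypes' full column profiles, resolved
through the column maps, and a classification of the two consensus residues:
identical, similar (same chemical class), divergent, or unpaired (either
side gapped). The chemical classes are a fixed, documented partition:
`{AVLIMC} {FWY} {STNQ} {KRH} {DE} {G} {P}`.

A paired position is an SDP of the target subtype iff

1. target consensus-residue conservation ≥ 0.85, and
2. the frequency of that identical residue among **all** rows of the
   comparison family at the paired column is ≤ 0.25.

The comparison denominator includes gap rows ("entire distribution"), in
deliberate contrast to the non-gap conservation statistic; a flag switches
to the non-gap convention. Candidacy is additionally restricted to target
columns with occupancy ≥ 0.80 (the landmark occupancy rule) so that a
poorly-occupied but locally-conserved column cannot masquerade as a
determinant; this restriction is an extension beyond the two written
criteria and can be switched off (`require_occupancy=False`).

Grids are pairwise only. A multi-subtype generalisation (progressive
alignment of several cores against the target) was considered and not built:
every downstream consumer, and the recovery analysis, is defined on one
target/comparison pair.

## Structure mapping and interface analysis

PDB files are parsed with gemmi, first coordinate model only; alternate
locations resolve to the highest-occupancy conformer (ties to altloc 'A');
hydrogens are parsed but excluded from SASA and contact distances by default
(a ~2 Å crystal structure models none). Consensus-to-chain mapping reuses
the global aligner on the chain's one-letter sequence — pairing by alignment
rather than residue numbering tolerates differently modelled ranges — and
reports percent identity so low-confidence maps are visible.

Ligand contacts: a residue is in contact when its minimum heavy-atom
distance to any ligand heavy atom is ≤ 4.0 Å, cutoff inclusive.

Superposition is closed-form Kabsch (SVD with a determinant correction to
force a proper rotation); RMSD is computed over Cα pairs obtained from the
chain-versus-chain sequence alignment with Cα present on both sides. Which
residues a crystallographic protomer comparison pairs depends on the
modelled ranges; alignment-based all-common-Cα pairing is the convention
here, so paired-atom counts can drift by a few residues relative to other
tools' choices.

SASA is Shrake–Rupley: each atom's extended sphere (van der Waals radius +
1.4 Å probe) is sampled with 960 deterministic golden-spiral points, and the
accessible fraction is the share of points outside every neighbour's
extended sphere. Radii: C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20,
default 1.70 Å. With 960 points, single-sphere areas match the analytic
value to well under 1 % and two-body burials match a 10⁵-point dense
quadrature within 2 %. Buried interface area per protomer is
`SASA(chain alone) − SASA(chain in complex)` over heavy atoms; interface
residues are those burying more than 0.1 Å² (a floor just above quadrature
noise). This is a standard geometric SASA-difference definition; tools that
add thermodynamic significance scoring to interfaces will report the same
areas but different residue significance calls.

## Mass analysis

Average protein masses use the standard residue-mass table (IUPAC average
atomic weights): sum of residue masses plus one water, reported in kDa
(display rounding to 1 decimal; comparisons against rounded literature
values should use nearest-kDa rounding). Assembly masses are plain
stoichiometric sums — noncovalent association adds no water correction.
Condensation-product masses are monoisotopic: `mass(acid) + mass(amine) −
mass(H₂O)` from a documented monoisotopic element table, for matching
extracted-ion chromatogram masses. His-tagged expression constructs should
be passed as the tag-cleaved sequence actually measured; the package
computes the mass of exactly the sequence it is given and makes no construct
assumptions.

Population calling on mass-photometry event lists is a one-dimensional
Gaussian mixture fitted by expectation-maximisation: k-means++ seeding from
the given seed, log-space responsibilities, convergence when the mean
log-likelihood changes by < 1e-8, at most 500 iterations (non-convergence is
an error carrying the iteration count, never a silent partial fit). The EM
is implemented in-package rather than delegated so that the degenerate cases
keep their exact semantics: k = 1 returns the closed-form sample mean and
(population) standard deviation, and identical events yield sd exactly 0. A
variance floor of 1e-12 kDa² guards collapsing components for k > 1.
Components are reported sorted by mean; counts are weight-apportioned
retained events, rounded. Events below the instrument floor (default
30 kDa — small carrier proteins near 10 kDa register only as unreliable
signals around 29–35 kDa on ratiometric instruments) are excluded before
fitting. Event counts depend on acquisition length and are not comparable
across experiments; means, widths and weights are.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (spec, seed), using numpy's PCG64;
within this implementation identical calls are bit-for-bit reproducible.
(Cross-language ports reproduce the distributional properties, not the
stream, which is why tests assert statistics rather than stream identity
except within this package.)

* **Families** draw each occupied cell independently: consensus residue with
  probability = the column's conservation level, otherwise uniform over the
  19 other canonical residues; gaps are placed uniformly to hit the
  occupancy level exactly (rounded to whole rows). There is no
  phylogenetic correlation between rows, no indel process, and no
  position-specific substitution preferences. Passing recovery tests on
  these families therefore demonstrates the *statistical machinery* —
  thresholds, denominators, tie rules — not robustness to tree-structured
  correlation, which real subtype families have.
* **Subtype pairs** share one template; at planted positions the comparison
  family carries the planted residue in exactly `floor(ceiling · n)` rows
  and never as noise, so the "entire distribution" frequency is controlled
  exactly — including just above the 0.25 threshold, where recovery must
  fail. Default generation conditions for recovery analyses: template
  length 450, 200 sequences per subtype, conservation 0.95, 5 planted
  positions, comparison ceiling 0.10 — family sizes and conservation chosen
  to match a mid-sized curated subtype set.
* **Structures** are Cα-only chains (3.8 Å spacing, extended or ideal-helix
  geometry) with single-atom ligands placed so the minimum distance to the
  anchor residue is exact, and dimers built by an explicit rigid transform.
  They exercise distance bookkeeping, superposition and SASA exactly, but
  contain no side chains, no packing, and no realistic interface chemistry.
* **Mass events** are i.i.d. Gaussian-mixture draws with multinomial
  population counts; real landing-event lists have mass-dependent detection
  efficiency and baseline artefacts the generator does not model.

## Problem sizes and determinism

Recovery and mixture analyses run at the sizes above (450 × 200 × 2
alignments; 5 000 events), which complete in seconds on one CPU; the dense
SASA oracle uses 10⁵ quadrature points on small atom sets. All stochastic
steps take explicit seeds, and the orchestrated pipeline writes a manifest
(thresholds, input SHA-256 digests, seed, per-stage row counts) such that
rerunning an identical configuration reproduces byte-identical outputs.

## Known limitations

* SDP analysis assumes the two consensus cores are globally homologous;
  grossly non-homologous cores still produce an alignment, flagged only by
  low percent identity.
* The consensus collapses each column to one residue; positions where a
  subtype splits between two residues (bimodal columns) fall below the 0.85
  conservation bar and are invisible to the SDP rule by construction.
* Buried-area values depend mildly on the radius table and probe; numbers
  are comparable across runs of this package, and with other tools only to
  within a few percent.
* The mixture model assumes Gaussian populations; strongly skewed or
  heavy-tailed event distributions will bias means outward.
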