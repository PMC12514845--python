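# Methods

## Model and assumptions

`halobond` treats a halogen bond as a purely geometric object: a
carbon-bonded halogen X whose σ-hole (the positive electrostatic cap
opposite the C–X bond) faces an electron-rich acceptor. No energies,
charges or orbital terms are computed; the method is empirical
throughout. The working assumption is that genuine halogen bonds in
well-determined structures cluster tightly in a few geometric
descriptors, so the distance of a candidate's descriptors from the bulk
of a reference distribution is a usable quality signal.

Descriptors per candidate:

| descriptor | definition | defined for |
|---|---|---|
| d | X···acceptor-point distance (Å) | both types |
| VdW overlap | r_X + r_Y − d (Å); positive = closer than VdW contact | atomic acceptors |
| θ1 | angle C–X···acceptor-point (°) | both types |
| θ2 | angle X···Y–Y′, Y′ a covalent neighbor of the acceptor (°) | atomic acceptors |

For π acceptors the acceptor point is the unweighted centroid of the
aromatic ring; θ2 and the VdW overlap are undefined there, and the score
aggregates over the two remaining descriptors only. The VdW overlap is
reported but not scored: it is a deterministic function of d and the
radii, so scoring it would double-count the distance.

## Detection rules

* Halogen sites: F/Cl/Br/I atoms whose compound is not on the packaged
  exclusion list (halide ions, halogen–metal complexes, halogen acids;
  114 component codes), bonded to exactly one carbon. Connectivity comes
  from a CCD-style dictionary (full dumps or blocks embedded in the
  structure file, embedded winning on conflict); without one, a
  per-element covalent-distance fallback fires (C–X cutoffs 1.9/1.95/
  2.05/2.25 Å for F/Cl/Br/I) and is logged. Halogens in alternate
  conformations are skipped entirely.
* Atomic acceptors: O/S atoms of canonical amino acids whose covalent
  heavy-atom neighbors are all carbon, from a static per-residue
  connectivity table (backbone O/OXT, Ser OG, Thr OG1, Tyr OH, Asp
  OD1/OD2, Glu OE1/OE2, Asn OD1, Gln OE1, Cys SG, Met SD), within
  4.0 Å inclusive. Waters are never acceptors — their θ2 is undefined.
  Contacts within the halogen's own residue are ignored. A survey mode
  widens discovery to O/N/S/P/Se in any organic compound for mining
  statistics, but such candidates are not scored.
* π acceptors: His (5-ring), Phe/Tyr (6-ring) and Trp side chains with
  all ring atoms present; centroid within 6.0 Å inclusive. The
  tryptophan indole contributes its pyrrole and benzene rings as two
  separate π systems by default, letting downstream selection keep the
  better-scoring one; a `trp_rings="whole"` switch uses the single
  9-atom centroid instead. Incomplete rings are skipped with a logged
  reason.
* θ1 filter: strictly θ1 > 90°, applied identically in scoring and
  calibration. The boundary value 90.0° is rejected.
* Symmetry mates are not generated; only explicit atoms are scanned.
  Disulfide partners of Cys SG are not resolved across residues, so a
  disulfide sulfur still scores as S–C; given the rarity of
  halogen···disulfide contacts this simplification is accepted.

## Scoring

Score_geom(value, Q1, Q3) = max((value−Q3)/IQR, (Q1−value)/IQR, 0);
HalBS is the maximum of the per-descriptor scores. Classification:
preferred at exactly 0 (box edges inclusive), allowed in (0, 1.5],
outlier strictly above 1.5; the 1.5 comparison is an exact
floating-point comparison, documented rather than toleranced. Reference
cells with non-positive IQR are rejected at load time, never divided by.

When the acceptor has several covalent neighbors (Met SD: CG and CE), θ2
is computed per neighbor and the neighbor with the lowest θ2 score is
used — a permissive choice that avoids penalizing a valid geometry for
an arbitrary neighbor pick. Calibration, which runs before any scores
exist, instead records the first neighbor in the connectivity table
(CG), keeping its θ2 population single-valued.

Per halogen, the lowest-HalBS candidate (atomic and π pooled) is
selected and reported; ties break atomic-over-π, then smaller d, then
residue order, purely for determinism. Candidates whose category has no
reference cell (e.g. iodine···Trp) are reported with geometry and an
explicit unscored reason; they never enter the per-model count or mean.
The per-model summary averages selected, scored bonds only, and reports
the mean as missing (not zero) when there are none.

Scoring accepts any halogen-containing compound class (ligand, modified
residue, nucleotide); only calibration restricts to ligand→protein
pairs.

## Reference statistics

The packaged table `reference_stats_synthetic.tsv` is a synthetic
stand-in, as its name states: per-category n and medians follow
published census values for ligand–protein halogen bonds (e.g. θ1
medians 132/143/154/169° for F/Cl/Br/I against O–C acceptors, π
distances around 4.8 Å, 5.1 Å for iodine), while Q1/Q3/MAD are plausible
spreads chosen once (distance IQR ≈ 0.3 Å atomic / 0.7 Å π, angle IQRs
≈ 17–36°, mean set to the median, MAD to IQR/2). Scores against this
table are indicative only; serious use should recalibrate or supply a
measured table (`ReferenceStats.from_tsv`).

Calibration quality thresholds (defaults): halogen B-factor ≤ 100 Å²,
per-compound RSCC ≥ 0.9 for both partners, resolution ≤ 2.5 Å, at least
5 observations per cell. Boundary values pass; missing metadata rejects
the observation as unverifiable rather than assuming quality. RSCC and
resolution are consumed from sidecar TSVs (`entry_id, chain,
residue_seq, compound_id, rscc` and `entry_id, resolution, r_factor,
r_free, mean_b`); density fit is never computed here. Quartiles use
linear interpolation between closest ranks (numpy's default, R type 7) —
the estimator is configurable because Q1/Q3 feed the score directly.
MAD is the unscaled median absolute deviation.

## Van der Waals radii

The paper trail for halogen-bond work cites the standard radii
compilations; this package ships the Bondi values (F 1.47, Cl 1.75,
Br 1.85, I 1.98, O 1.52, S 1.80 Å, plus C/N/P/Se for survey mode) as an
editable TSV, so users can substitute a different compilation without
touching code.

## Synthetic fixtures

The fixture generator emulates exactly what the detector touches: a
two-atom halogenated ligand with embedded CCD connectivity, and a
minimal protein fragment carrying the acceptor — a backbone carbonyl
(O–C), a Met side chain with both SD neighbors (S–C), or a complete
idealized aromatic ring (planar polygon, 1.39 Å edges; Trp as a full
fused indole) whose centroid sits at the prescribed distance. Atom
placement is analytic: θ1 is set at the halogen, θ2 at the acceptor, and
the whole model is passed through a seeded uniformly-random rigid motion
so no fixture is axis-aligned. Coordinates are written at 7 decimals,
which keeps round-trip geometry within 1e−6 Å / 1e−4°. Randomness is
numpy's PCG64 generator, seeded, so identical seeds give byte-identical
files.

What the fixtures do *not* emulate: chemically realistic ligands beyond
the C–X unit, crystal packing and symmetry mates, experimental noise in
coordinates, correlated descriptors, or real electron density (RSCC
values in synthetic corpora are assigned, not measured). Tests passing
on fixtures therefore demonstrate the correctness of the geometry,
filtering, scoring and calibration machinery — not the empirical
validity of any particular reference table on real structures.

Synthetic corpora draw each descriptor i.i.d. from truncated normal
laws (defaults: d ~ N(3.5, 0.2) Å atomic / N(4.8, 0.35) Å π, θ1 ~
N(160, 10)° atomic / N(140, 12)° π, θ2 ~ N(105, 8)°), truncated to the
detection shell and θ1 > 90° so every draw is detectable and quartile
recovery is unbiased; the analytic quartiles of the truncated laws are
returned alongside for parameter-recovery tests. The shipped tests
recover quartiles at n = 50 and n = 500 within three Monte-Carlo
standard errors; problem sizes were chosen as the smallest that make
those standard errors meaningfully tight.

## Numerical choices and degenerate inputs

* Angles are computed in double precision with the cosine clamped to
  [−1, 1], so collinear arms never raise domain errors; zero-length arms
  do raise.
* Distance shells are inclusive at the cutoff (d ≤ 4.0 / 6.0 Å).
* Mining acceptor selection (calibration) maximizes θ1; exact ties break
  by smaller d, then residue order.
* Empty inputs are ordinary results, not errors: a structure without
  halogens yields an empty report with count 0; an empty calibration
  corpus yields an empty table with a warning.
* Multi-model files score model 1 only by default (crystallographic
  convention); a flag iterates ensembles.

## Known limitations

* Nitrogen acceptors (histidine N) are out of scope: their availability
  depends on protonation state, which coordinates alone do not settle.
* Hydrogen bonds to halogens, water acceptors, peptide-bond π systems,
  and perpendicular-distance π descriptors are not implemented.
* The packaged reference table is synthetic (see above); per-model mean
  HalBS values computed against it should not be compared across
  publications.
* Occupancy-weighted positions are never used; raw coordinates only.
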