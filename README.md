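# halobond

Detection, geometric scoring and calibration of **ligand–protein halogen
bonds** in macromolecular structure models (mmCIF / PDB).

Halogen bonds are polar interactions between a carbon-bonded halogen atom
(F, Cl, Br, I) and an electron-rich acceptor. The σ-bond to carbon
polarizes the halogen, leaving a patch of positive potential — the
σ-hole — opposite the bond, so the interaction is strongly directional.
Despite their role in drug design, halogen bonds are usually ignored by
structure-validation pipelines. `halobond` finds candidate halogen bonds
in a structure model, measures their geometry, and grades each one
against empirical reference distributions, for crystallographers and
ligand-validation pipelines that want halogen-bond geometry flagged the
same way rotamers or Ramachandran angles are.

## The score

Two interaction types are considered:

* **C–X··Y** — halogen to an O or S atom whose covalent neighbors are all
  carbon ("O–C" / "S–C" acceptor classes) in a canonical amino acid,
  within 4 Å. Descriptors: distance *d*, Van der Waals overlap
  (*r*<sub>X</sub> + *r*<sub>Y</sub> − *d*), the angle θ₁ = ∠(C, X, Y) at
  the halogen, and θ₂ = ∠(X, Y, Y′) at the acceptor (Y′ its covalent
  neighbor).
* **C–X···π** — halogen to the aromatic side chain of His, Phe, Tyr or
  Trp, represented by its ring centroid, within 6 Å. Descriptors: *d*
  and θ₁ only; θ₂ and the VdW overlap are undefined.

Candidates with θ₁ ≤ 90° are discarded (the acceptor cannot reach the
σ-hole), waters are never acceptors, and halogens in alternate
conformations are skipped.

Each descriptor is scored against the reference boxplot of its
(halogen × acceptor-class) category:

```
Score_geom = max( (value − Q3)/IQR , (Q1 − value)/IQR , 0 ),   IQR = Q3 − Q1
```

i.e. the number of IQRs the value lies outside the box, and the overall
bond score is the least favorable feature:

```
HalBS = max( Score_d , Score_θ1 [, Score_θ2 if defined] )
```

HalBS = 0 is **preferred** (every descriptor within its box),
0 < HalBS ≤ 1.5 **allowed** (within the whiskers), and HalBS > 1.5 an
**outlier** that deserves critical inspection. When one halogen has
several possible acceptors, the bond with the lowest HalBS is reported.
Per model, the bond count and mean HalBS are summarized.

The packaged reference table (`data/reference_stats_synthetic.tsv`) is a
labelled synthetic stand-in — published per-category observation counts
and medians with plausible synthetic spreads. For production use,
recalibrate on a corpus of well-determined structures with
`halobond calibrate`, which applies the standard quality filters
(halogen B-factor ≤ 100 Å², per-compound RSCC ≥ 0.9 for both partners,
resolution ≤ 2.5 Å), keeps ligand→protein bonds only, selects one
acceptor per halogen (θ₁ closest to 180°), and computes per-category
boxplot statistics (cells with fewer than five observations are
omitted).

## Worked example

Generate a synthetic structure containing one Br···O bond with prescribed
geometry, then score it:

```sh
$ halobond fixtures --halogen Br --acceptor O-C --distance 3.45 \
      --theta1 160 --theta2 110 --seed 3 -o example.cif
$ halobond score example.cif
```

```
chain  residue  seq  atom  halogen  ...  acceptor_class  d     vdw_overlap  theta1  theta2  score_distance  score_theta1  score_theta2  halbs  classification
A      LIG      371  BR1   Br       ...  O-C             3.45  -0.08        160.0   110.0   0.00            0.00          0.00          0.00   preferred
```

with the per-model summary on stderr:

```
example.cif: 1 halogen bond(s), mean HalBS 0.00
```

The bromine sits 3.45 Å from the backbone carbonyl oxygen of Ala A97 —
just outside VdW contact (overlap −0.08 Å) — with θ₁ = 160° placing the
oxygen in the σ-hole and θ₂ = 110° within the expected 90–120° range.
Every descriptor falls inside its reference box, so each per-parameter
score is 0.00 and the bond is classified *preferred*. `--format json`
gives the same report at full precision; `--format mmcif-block` emits the
per-model `_halobond_summary` key-value block.

`halobond calibrate *.cif --model-metadata meta.tsv --rscc rscc.tsv
--out-stats stats.tsv` writes a reference table that `halobond score
--stats stats.tsv` consumes directly.

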