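# mirrorsep

Separate properly oriented protein models from their mirror images.

Structure reconstruction from contact maps cannot recover chirality: the
same inter-residue distances are satisfied by a fold and by its mirror
image, so reconstruction pipelines emit a mixture of properly oriented
and mirror models. `mirrorsep` implements the statistics that tell the
two groups apart:

* **chirality statistics** — the Φ⁺ ratio (fraction of positive backbone
  φ angles; right-handed helices have negative φ),
* **Ramachandran analysis** — favored/allowed/outlier region fractions
  with the four-class scheme (general / Gly / Pro / pre-Pro) and two
  knowledge-based dihedral scores (a Ramachandran-preference potential
  and a P(amino&nbsp;acid&nbsp;|&nbsp;φ,ψ) score),
* **orientation assignment** — Kabsch superposition of each model
  against a reference structure and against its ideal mirror image,
  plus a reference-free two-cluster split of per-model scores,
* **group statistics** — per-term Mann–Whitney significance matrices,
  normalised term-mean (NMT) maps, per-domain summaries and the
  cross-domain correlations,
* **synthetic data** — a deterministic internal-coordinate generator of
  labeled proper/mirror helical-bundle ensembles with three difficulty
  regimes (`distinct`, `moderate`, `indistinct`).

The bundled Ramachandran tables are built analytically from a documented
Gaussian-mixture prior over the canonical φ/ψ basins. They support
*relative* proper-vs-mirror comparisons; absolute score values do not
match Rosetta's `rama` / `p_aa_p` terms. Externally computed energy
terms (e.g. a Rosetta score file re-exported as CSV with a `model_id`
column) can be merged into the significance analysis unchanged.

## CLI

```sh
# generate a synthetic labeled study batch (PDB files + labels.csv per domain)
mirrorsep simulate --domains 11 --regime distinct --n-proper 20 --n-mirror 20 \
                   --seed 1 --out sim/

# label models in a directory against a reference structure
mirrorsep classify --reference ref.pdb --models models/ --out labels.csv

# run the full analysis (simulate or pdb-dir mode) from a JSON config
mirrorsep analyze --config run.json

# regenerate the Ramachandran tables as CSV grids
mirrorsep build-tables --out tables/
```

`analyze` writes `labels.csv`, `term_values.csv`,
`significance_matrix.csv` (per term: `<term>_p` p-value and
`<term>_sig` 0/1 flag), `nmt_proper.csv`, `nmt_mirror.csv`,
`domain_summaries.csv`, `correlations.json` and `run_log.json` to the
configured output directory. A minimal simulate-mode config:

```json
{"mode": "simulate", "out_dir": "out", "seed": 1,
 "n_domains": 11, "regime": "distinct", "n_proper": 20, "n_mirror": 20}
```

## Library example

```python
import mirrorsep as ms

spec = ms.EnsembleSpec(sequence="AELKQRM" * 6 + "gnstd" + "AELKQRM" * 6,
                       n_proper=20, n_mirror=20, regime="moderate", seed=1)
ens = ms.make_ensemble(spec)
for labeled in ens.models[:3]:
    label = ms.assign_orientation(labeled.model, ens.reference)
    print(labeled.model.id, label.value.value,
          round(ms.rama_score(labeled.model), 1),
          round(ms.phi_plus_ratio(labeled.model).phi_plus_ratio, 2))
```
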