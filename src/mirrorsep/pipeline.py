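"""End-to-end orchestration: simulate or ingest, label, score, summarise.

``run_analysis`` produces the full artifact set for a study batch:

* ``labels.csv``               per-model orientation labels and RMSDs
* ``term_values.csv``          per-model score terms
* ``significance_matrix.csv``  domain x term p-values and 0/1 flags
* ``nmt_proper.csv`` / ``nmt_mirror.csv``  normalised term-mean maps
* ``domain_summaries.csv``     per-domain group means and ratios
* ``correlations.json``        the three cross-domain correlations
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import chirality, group_stats, ramachandran, synthetic_data
from .structure_io import StructureModel, load_score_table, read_pdb

logger = logging.getLogger(__name__)

DIHEDRAL_TERMS = ("rama", "p_aa_p", "phi_plus_ratio")


@dataclass
class RunConfig:
    mode: str = "simulate"              # 'simulate' | 'pdb-dir'
    out_dir: str = "mirrorsep_out"
    seed: int = 0
    alpha: float = 0.05
    terms: tuple = DIHEDRAL_TERMS
    handedness: str = "right"
    # simulate mode
    n_domains: int = 11
    regime: str = "distinct"
    n_proper: int = 20
    n_mirror: int = 20
    # pdb-dir mode
    input_dir: Optional[str] = None
    reference_pdb: Optional[str] = None
    # optional externally computed terms
    score_csv: Optional[str] = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not self.terms and not self.score_csv:
            raise ValueError("select at least one term or provide a score CSV")
        if self.mode not in ("simulate", "pdb-dir"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "terms" in data:
            data["terms"] = tuple(data["terms"])
        return cls(**data)


def score_model(model: StructureModel, reference: StructureModel,
                tables: ramachandran.RamaTables | None = None) -> dict:
    """All per-model quantities for one model against its reference."""
    tables = tables or ramachandran.default_tables()
    label = chirality.assign_orientation(model, reference)
    stats = chirality.phi_plus_ratio(model)
    return {
        "model_id": model.id,
        "label": label.value.value,
        "rmsd_to_ref": label.rmsd_to_ref,
        "rmsd_to_mirror_ref": label.rmsd_to_mirror_ref,
        "phi_plus_ratio": stats.phi_plus_ratio,
        "rama": ramachandran.rama_score(model, tables),
        "p_aa_p": ramachandran.p_aa_p_score(model, tables),
    }


def _collect_domain_table(ensemble: synthetic_data.LabeledEnsemble,
                          tables: ramachandran.RamaTables) -> pd.DataFrame:
    rows = []
    for lm in ensemble.models:
        row = score_model(lm.model, ensemble.reference, tables)
        row["domain"] = ensemble.domain_id
        row["true_label"] = lm.true_label
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the whole study and write the artifact set; returns the paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("=== mirrorsep analysis: mode=%s seed=%d alpha=%g ===",
                config.mode, config.seed, config.alpha)
    tables = ramachandran.default_tables()

    if config.mode == "simulate":
        batch = synthetic_data.make_study_batch(
            config.n_domains, regime=config.regime, seed=config.seed,
            n_proper=config.n_proper, n_mirror=config.n_mirror,
            handedness=config.handedness)
        per_model = pd.concat(
            [_collect_domain_table(e, tables) for e in batch], ignore_index=True)
    else:
        if not config.input_dir or not config.reference_pdb:
            raise ValueError("pdb-dir mode needs input_dir and reference_pdb")
        reference = read_pdb(config.reference_pdb)
        rows = []
        for path in sorted(Path(config.input_dir).glob("*.pdb")):
            model = read_pdb(path)
            row = score_model(model, reference, tables)
            row["domain"] = Path(config.input_dir).name
            row["true_label"] = ""
            rows.append(row)
        if not rows:
            raise ValueError(f"no .pdb files in {config.input_dir}")
        per_model = pd.DataFrame(rows)

    if config.score_csv:
        external = load_score_table(config.score_csv)
        per_model = per_model.merge(external, left_on="model_id",
                                    right_index=True, how="left")
        term_cols = list(config.terms) + list(external.columns)
    else:
        term_cols = list(config.terms)

    artifacts: dict[str, Path] = {}

    labels = per_model[["model_id", "domain", "label", "true_label",
                        "rmsd_to_ref", "rmsd_to_mirror_ref", "phi_plus_ratio"]]
    artifacts["labels"] = out_dir / "labels.csv"
    labels.to_csv(artifacts["labels"], index=False)

    term_values = per_model[["model_id", "domain", "label"] + term_cols]
    artifacts["term_values"] = out_dir / "term_values.csv"
    term_values.to_csv(artifacts["term_values"], index=False)

    # group statistics need both orientation groups per domain
    domain_tables = {
        d: g[["label"] + term_cols].reset_index(drop=True)
        for d, g in per_model.groupby("domain", sort=False)
    }
    usable = {d: t for d, t in domain_tables.items()
              if (t["label"] == "proper").sum() >= 3
              and (t["label"] == "mirror").sum() >= 3}
    if not usable:
        logger.warning("no domain has >= 3 models in both groups; "
                       "skipping group statistics")
        _write_run_log(out_dir, config, artifacts)
        return artifacts

    flags, pvals = group_stats.significance_matrix(usable, alpha=config.alpha)
    sig = pd.concat(
        [pvals.add_suffix("_p"), flags.astype(int).add_suffix("_sig")], axis=1)
    sig.index.name = "domain"
    artifacts["significance_matrix"] = out_dir / "significance_matrix.csv"
    sig.to_csv(artifacts["significance_matrix"])

    for group in ("proper", "mirror"):
        means = pd.DataFrame({
            d: t[t["label"] == group][term_cols].mean()
            for d, t in usable.items()
        }).T
        # a term whose means vanish in this group (e.g. the phi+ ratio of
        # ideal proper models) cannot be normalised; report it as all-zero
        zero_cols = [c for c in means.columns if means[c].abs().max() == 0]
        for col in zero_cols:
            logger.warning("NMT (%s): term %r has all-zero means", group, col)
        nmt = group_stats.nmt_normalize(means.drop(columns=zero_cols))
        for col in zero_cols:
            nmt[col] = 0.0
        nmt = nmt[list(means.columns)]
        nmt.index.name = "domain"
        key = f"nmt_{group}"
        artifacts[key] = out_dir / f"{key}.csv"
        nmt.to_csv(artifacts[key])

    model_tables = {
        d: g[["label", "rmsd_to_ref", "phi_plus_ratio"]].reset_index(drop=True)
        for d, g in per_model.groupby("domain", sort=False) if d in usable
    }
    summaries = group_stats.domain_summaries(model_tables, flags)
    summary_df = pd.DataFrame([vars(s) for s in summaries])
    artifacts["domain_summaries"] = out_dir / "domain_summaries.csv"
    summary_df.to_csv(artifacts["domain_summaries"], index=False)

    correlations = _correlations(summary_df)
    artifacts["correlations"] = out_dir / "correlations.json"
    with open(artifacts["correlations"], "w") as fh:
        json.dump(correlations, fh, indent=2, sort_keys=True)

    _write_run_log(out_dir, config, artifacts)
    logger.info("wrote %d artifacts to %s", len(artifacts), out_dir)
    return artifacts


def _correlations(summary_df: pd.DataFrame) -> dict:
    """The three cross-domain correlations of the study."""
    out = {}
    if len(summary_df) < 3:
        return out
    ratio = (summary_df["phi_plus_ratio_proper"]
             / summary_df["phi_plus_ratio_mirror"])
    pairs = {
        "phi_ratio_vs_mean_rmsd_proper":
            (ratio, summary_df["mean_rmsd_proper"]),
        "phi_ratio_vs_structural_difference":
            (ratio, summary_df["structural_difference"]),
        "n_significant_vs_structural_difference":
            (summary_df["n_significant_terms"].astype(float),
             summary_df["structural_difference"]),
    }
    for name, (x, y) in pairs.items():
        try:
            r, p = group_stats.pearson(x, y)
            out[name] = {"r": r, "p_value": p}
        except ValueError as exc:
            logger.warning("correlation %s skipped: %s", name, exc)
    return out


def _write_run_log(out_dir: Path, config: RunConfig,
                   artifacts: dict[str, Path]) -> None:
    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
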