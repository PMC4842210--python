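"""Per-energy-term group statistics across proper/mirror model ensembles.

The central question is whether a score term separates the properly
oriented group from the mirror group of each domain.  The test is a
two-sided Mann-Whitney U: exact permutation enumeration when both groups
have at most MAX_EXACT_N values, tie-corrected normal approximation
otherwise.  A Welch t-test is available behind ``method="welch"`` for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

MAX_EXACT_N = 8
DEFAULT_ALPHA = 0.05


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x against y via midranks (ties count half)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p-value of the U statistic.

    Enumerates every split of the pooled sample; under the permutation
    null U is symmetric about nm/2 (with or without ties), so the
    two-sided p is the mass at least as far from nm/2 as observed.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    offset = n * (n + 1) / 2.0
    mid = n * m / 2.0
    u_obs = ranks[:n].sum() - offset
    dev_obs = abs(u_obs - mid)
    hits = 0
    total = comb(n + m, n)
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mid) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


def mann_whitney(x, y) -> tuple[float, float]:
    """(U, two-sided p); exact for small groups, else tie-corrected normal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    u = _u_statistic(x, y)
    if len(x) <= MAX_EXACT_N and len(y) <= MAX_EXACT_N:
        return u, _exact_mwu_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


@dataclass
class TermSummary:
    term: str
    mean_proper: float
    sd_proper: float
    mean_mirror: float
    sd_mirror: float
    p_value: float
    significant: bool
    mean_ratio: float


def term_significance(values_proper, values_mirror, alpha: float = DEFAULT_ALPHA,
                      term: str = "", method: str = "mannwhitney") -> TermSummary:
    """Compare one score term between the proper and mirror groups."""
    x = np.asarray(values_proper, dtype=float)
    y = np.asarray(values_mirror, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(
            f"term {term or '<unnamed>'}: need >= 3 values per group "
            f"(got {len(x)}, {len(y)})"
        )
    if method == "mannwhitney":
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0  # all values identical: no evidence whatsoever
        else:
            _, p = mann_whitney(x, y)
    elif method == "welch":
        if x.std() == 0 and y.std() == 0:
            p = 1.0 if x.mean() == y.mean() else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    mean_m = float(y.mean())
    return TermSummary(
        term=term,
        mean_proper=float(x.mean()),
        sd_proper=float(x.std(ddof=1)),
        mean_mirror=mean_m,
        sd_mirror=float(y.std(ddof=1)),
        p_value=p,
        significant=bool(p < alpha),
        mean_ratio=float(x.mean() / mean_m) if mean_m != 0 else np.nan,
    )


def significance_matrix(term_tables: dict[str, pd.DataFrame],
                        alpha: float = DEFAULT_ALPHA,
                        method: str = "mannwhitney",
                        bh_correct: bool = False,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Domain x term significance flags and p-values.

    ``term_tables`` maps domain id -> per-model DataFrame with a ``label``
    column ('proper'/'mirror') plus one numeric column per term.  Returns
    (flags, pvalues), both domains x terms.  With ``bh_correct`` the flags
    use Benjamini-Hochberg across terms within each domain.
    """
    domains = list(term_tables)
    if not domains:
        raise ValueError("no domains given")
    terms = [c for c in term_tables[domains[0]].columns if c != "label"]
    pvals = pd.DataFrame(index=domains, columns=terms, dtype=float)
    flags = pd.DataFrame(index=domains, columns=terms, dtype=bool)
    for d in domains:
        df = term_tables[d]
        proper = df[df["label"] == "proper"]
        mirror = df[df["label"] == "mirror"]
        row_p = []
        for t in terms:
            summary = term_significance(proper[t], mirror[t], alpha=alpha,
                                        term=t, method=method)
            pvals.loc[d, t] = summary.p_value
            row_p.append(summary.p_value)
        if bh_correct:
            rejected = _benjamini_hochberg(np.array(row_p), alpha)
            flags.loc[d, :] = rejected
        else:
            flags.loc[d, :] = np.array(row_p) < alpha
    return flags, pvals


def _benjamini_hochberg(pvals: np.ndarray, alpha: float) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    rejected = np.zeros(m, dtype=bool)
    max_k = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= alpha * rank / m:
            max_k = rank
    rejected[order[:max_k]] = True
    return rejected


def nmt_normalize(means: pd.DataFrame) -> pd.DataFrame:
    """Normalise a domain x term matrix of means to [-1, 1] per term.

    Each term column is divided by the maximum absolute mean over domains,
    so per term at least one domain attains +/-1.
    """
    if means.empty:
        raise ValueError("empty mean matrix")
    out = means.copy().astype(float)
    for col in out.columns:
        denom = out[col].abs().max()
        if denom == 0:
            raise ValueError(f"term {col!r}: all domain means are zero")
        out[col] = out[col] / denom
    return out


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p (t-test, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance sample")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DomainSummary:
    domain: str
    mean_rmsd_proper: float
    mean_rmsd_mirror: float
    structural_difference: float  # mean RMSD proper / mean RMSD mirror
    phi_plus_ratio_proper: float
    phi_plus_ratio_mirror: float
    n_significant_terms: int


def domain_summaries(model_tables: dict[str, pd.DataFrame],
                     flags: pd.DataFrame | None = None) -> list[DomainSummary]:
    """Per-domain group means feeding the correlation analyses.

    ``model_tables`` maps domain -> per-model DataFrame with columns
    ``label``, ``rmsd_to_ref``, ``phi_plus_ratio``.  ``flags`` is the
    output of :func:`significance_matrix` (optional; significant-term
    counts are 0 without it).
    """
    out = []
    for d, df in model_tables.items():
        proper = df[df["label"] == "proper"]
        mirror = df[df["label"] == "mirror"]
        if proper.empty or mirror.empty:
            raise ValueError(f"domain {d}: one of the groups is empty")
        mr_p = float(proper["rmsd_to_ref"].mean())
        mr_m = float(mirror["rmsd_to_ref"].mean())
        n_sig = int(flags.loc[d].sum()) if flags is not None else 0
        out.append(DomainSummary(
            domain=d,
            mean_rmsd_proper=mr_p,
            mean_rmsd_mirror=mr_m,
            structural_difference=mr_p / mr_m,
            phi_plus_ratio_proper=float(proper["phi_plus_ratio"].mean()),
            phi_plus_ratio_mirror=float(mirror["phi_plus_ratio"].mean()),
            n_significant_terms=n_sig,
        ))
    return out
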