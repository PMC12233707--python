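"""Fragment-level count matrix and negative-binomial differential abundance.

A deliberately simple estimator in the DESeq2 family: median-of-ratios
size factors, a per-fragment method-of-moments NB dispersion, and a
delta-method Wald test on log2 fold changes of group means, with
Benjamini-Hochberg adjustment.  No shrinkage, no outlier filtering, no
trended dispersion — the contract is simulation calibration, not parity
with any particular package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

LN2 = float(np.log(2.0))
ALPHA_FLOOR = 1e-8
ALPHA_CEIL = 10.0
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DesignInfo:
    """sample_id -> (timepoint, replicate); timepoints in design order."""

    samples: tuple[str, ...]
    timepoints: tuple[str, ...]
    replicates: tuple[int, ...]

    def __post_init__(self):
        if len({len(self.samples), len(self.timepoints), len(self.replicates)}) != 1:
            raise ValueError("samples/timepoints/replicates length mismatch")

    @property
    def timepoint_order(self) -> list[str]:
        seen: list[str] = []
        for t in self.timepoints:
            if t not in seen:
                seen.append(t)
        return seen

    def samples_at(self, timepoint: str) -> list[str]:
        return [s for s, t in zip(self.samples, self.timepoints) if t == timepoint]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "DesignInfo":
        req = {"sample_id", "timepoint", "replicate"}
        if not req.issubset(table.columns):
            raise ValueError(f"design table needs columns {sorted(req)}")
        return cls(
            samples=tuple(table["sample_id"].astype(str)),
            timepoints=tuple(table["timepoint"].astype(str)),
            replicates=tuple(int(r) for r in table["replicate"]),
        )

    @classmethod
    def read(cls, path: str | Path) -> "DesignInfo":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            dict(sample_id=self.samples, timepoint=self.timepoints, replicate=self.replicates)
        ).to_csv(path, sep="\t", index=False)


def count_matrix(frag_table: pd.DataFrame, design: DesignInfo) -> pd.DataFrame:
    """Fragment x sample integer matrix from the weighted fragment table.

    Weighted (fractional) multi-map counts are rounded half-to-even so
    the NB model sees integers; the index is "family_id:name".
    """
    from .fragannot import sample_columns

    samples = sample_columns(frag_table)
    missing = [s for s in design.samples if s not in samples]
    if missing:
        raise ValueError(f"design samples missing from fragment table: {missing}")
    cm = frag_table[list(design.samples)].copy()
    cm.index = frag_table["family_id"] + ":" + frag_table["name"]
    return np.round(cm).astype(int)


def size_factors(cm: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean 1.

    For each sample, the median over all-positive fragments of
    count / geometric-mean(count across samples).  When no fragment is
    positive in every sample, falls back to total-count ratios with a
    warning.
    """
    X = cm.to_numpy(dtype=float)
    positive = (X > 0).all(axis=1)
    if positive.any():
        logX = np.log(X[positive])
        log_geomean = logX.mean(axis=1, keepdims=True)
        ratios = np.exp(logX - log_geomean)
        sf = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no fragment with positive counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = X.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: a sample has zero total counts")
        sf = totals
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=cm.columns, name="size_factor")


def estimate_dispersion(values: Sequence[float]) -> float | None:
    """Method-of-moments NB dispersion of one normalized-count vector.

    alpha = max((s^2 - mean) / mean^2, 1e-8), capped at 10; Poisson-like
    vectors hit the floor.  A zero-mean vector has no defined dispersion
    (None): the fragment is excluded from testing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("dispersion needs >= 2 values")
    m = x.mean()
    if m == 0:
        return None
    s2 = x.var(ddof=1)
    return float(min(max((s2 - m) / m**2, ALPHA_FLOOR), ALPHA_CEIL))


def _pooled_dispersion(a: np.ndarray, b: np.ndarray) -> float | None:
    """Dispersion from pooled within-group residuals of two groups."""
    m = np.concatenate([a, b]).mean()
    if m == 0:
        return None
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    s2 = ss / (len(a) + len(b) - 2)
    return float(min(max((s2 - m) / m**2, ALPHA_FLOOR), ALPHA_CEIL))


def wald_test(
    cm: pd.DataFrame,
    design: DesignInfo,
    contrast: tuple[str, str],
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald test of ``contrast = (reference, treatment)`` timepoints.

    Per fragment: group means of normalized counts with pseudocount 0.5,
    log2fc = log2(mu_B / mu_A), a delta-method standard error
    se^2 = sum_g (1/mu_g + alpha) / (n_g ln^2 2) with the pooled
    within-group dispersion, and a two-sided p-value from a t reference
    with n_A + n_B - 2 degrees of freedom (the dispersion is estimated
    from that many residual df; at n = 3 vs 3 a normal reference is
    visibly anticonservative).  BH-adjusted p-values are appended.
    Fragments with all-zero counts in both groups are reported as NA.
    """
    ref_tp, alt_tp = contrast
    g_a = design.samples_at(ref_tp)
    g_b = design.samples_at(alt_tp)
    if len(g_a) < 2 or len(g_b) < 2:
        raise ValueError(f"both contrast groups need >= 2 samples: {contrast}")
    if sf is None:
        sf = size_factors(cm)
    norm = cm / sf
    A = norm[g_a].to_numpy(dtype=float)
    B = norm[g_b].to_numpy(dtype=float)
    base_mean = norm.to_numpy(dtype=float).mean(axis=1)

    n = cm.shape[0]
    df = len(g_a) + len(g_b) - 2
    log2fc = np.full(n, np.nan)
    se = np.full(n, np.nan)
    wald = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    for i in range(n):
        a, b = A[i], B[i]
        alpha = _pooled_dispersion(a, b)
        if alpha is None:
            continue  # degenerate: zero in both groups
        mu_a = a.mean() + PSEUDOCOUNT
        mu_b = b.mean() + PSEUDOCOUNT
        log2fc[i] = np.log2(mu_b / mu_a)
        se2 = ((1.0 / mu_a + alpha) / len(a) + (1.0 / mu_b + alpha) / len(b)) / LN2**2
        se[i] = np.sqrt(se2)
        wald[i] = log2fc[i] / se[i]
        pval[i] = min(2.0 * stats.t.sf(abs(wald[i]), df), 1.0)
    pval = np.where(np.isnan(pval), np.nan, np.clip(pval, np.nextafter(0, 1), 1.0))
    res = pd.DataFrame(
        dict(
            base_mean=base_mean,
            log2fc=log2fc,
            se=se,
            wald=wald,
            pvalue=pval,
            padj=adjust_bh(pval),
        ),
        index=cm.index,
    )
    return res


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = stats.false_discovery_control(p[mask], method="bh")
    return out


def significant(res: pd.DataFrame, padj_cutoff: float = 0.05, lfc_cutoff: float = 1.0) -> pd.Series:
    """Boolean labelling used downstream (volcano, reports)."""
    return (res["padj"] < padj_cutoff) & (res["log2fc"].abs() >= lfc_cutoff)


def write_de_table(
    res: pd.DataFrame,
    path: str | Path,
    padj_cutoff: float = 0.05,
    lfc_cutoff: float = 1.0,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = res.copy()
    out.insert(0, "fragment", res.index)
    out.insert(1, "family_id", [f.split(":", 1)[0] for f in res.index])
    out["significant"] = significant(res, padj_cutoff, lfc_cutoff)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path
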