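"""Microarray differential-expression chain: iterative Grubbs outlier
removal on replicate probes, probe-to-gene averaging, the Cyber-T
Bayesian-regularized t-test, and the ratio/p significance filter.

The probe table is a tidy DataFrame with columns
``gene, probe_id, condition, replicate, log2_intensity``.

Cyber-T regularizes each gene's variance toward a local background
estimate: genes are ordered by mean expression within a group, the
background s0^2 is the squared running mean of sample standard
deviations over a window of neighbouring genes, and the posterior
variance is

    s*^2 = (nu0 * s0^2 + (n - 1) * s^2) / (nu0 + n - 2).

The statistic is a Welch-type t on the regularized variances, with
Welch-Satterthwaite degrees of freedom plus 2*nu0 prior degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientReplicatesError

PROBE_COLUMNS = ("gene", "probe_id", "condition", "replicate", "log2_intensity")


@dataclass
class CyberTParams:
    """Window size (genes) for the variance background and prior df."""

    window: int = 101
    nu0: float = 10.0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.nu0 < 0:
            raise ValueError("nu0 must be >= 0")


@dataclass
class DEResult:
    gene: str
    mean_ratio: float  # linear fold change, higher direction
    t_reg: float
    p: float
    significant: bool


# ---------------------------------------------------------------------------
# Grubbs outlier removal


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size n."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return ((n - 1) / np.sqrt(n)) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    x, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs test; returns (kept, removed).

    Each iteration removes the single most extreme point iff
    G = max|x_i - mean| / sd exceeds the critical value; iteration stops
    when nothing is rejected or fewer than 3 points remain.  A zero
    standard deviation (constant data) removes nothing.
    """
    kept = np.asarray(x, dtype=float).copy()
    removed: list[float] = []
    while kept.size >= 3:
        mean = kept.mean()
        sd = kept.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(kept - mean)
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
        if g > grubbs_critical(kept.size, alpha):
            removed.append(kept[idx])
            kept = np.delete(kept, idx)
        else:
            break
    return kept, np.asarray(removed)


# ---------------------------------------------------------------------------
# Probe collapsing


def collapse_replicates(
    probes: pd.DataFrame, alpha: float = 0.05, apply_grubbs: bool = True
) -> pd.DataFrame:
    """Mean of replicate probes per gene and array, after outlier removal.

    Grubbs filtering is applied to the probe values within each
    gene x condition x replicate cell.  Returns a DataFrame indexed by
    gene with a (condition, replicate) column MultiIndex.  Genes losing
    all probes are dropped with a warning.
    """
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe table lacks columns {missing}")

    def _mean(vals: pd.Series) -> float:
        arr = vals.to_numpy(dtype=float)
        if apply_grubbs and arr.size >= 3:
            arr, _ = grubbs_filter(arr, alpha)
        if arr.size == 0:
            return np.nan
        return float(arr.mean())

    agg = (
        probes.groupby(["gene", "condition", "replicate"])["log2_intensity"]
        .apply(_mean)
        .unstack(["condition", "replicate"])
    )
    bad = agg.index[agg.isna().all(axis=1)]
    if len(bad):
        warnings.warn(f"{len(bad)} genes lost all probes and were dropped")
        agg = agg.drop(index=bad)
    return agg


# ---------------------------------------------------------------------------
# Cyber-T


def _background_variance(means: np.ndarray, variances: np.ndarray, window: int):
    """Local background variance: genes are ordered by mean expression and
    the per-gene standard deviations are averaged over a centred running
    window, then squared (the averaging scale used by the original
    Cyber-T tool; averaging raw variances instead makes the test
    noticeably conservative at small n)."""
    order = np.argsort(means, kind="stable")
    s0 = (
        pd.Series(np.sqrt(variances[order]))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    ) ** 2
    out = np.empty_like(s0)
    out[order] = s0
    return out


def cyber_t(
    groupA: pd.DataFrame | np.ndarray,
    groupB: pd.DataFrame | np.ndarray,
    prm: CyberTParams | None = None,
) -> pd.DataFrame:
    """Regularized two-sample t-test per gene.

    ``groupA``/``groupB`` are genes x replicates matrices on the log2
    scale with identical row order (a shared gene index when DataFrames).
    Returns a DataFrame with columns mean_a, mean_b, log2_ratio,
    fold_change, t_reg, df, p.
    """
    if prm is None:
        prm = CyberTParams()
    genes = None
    if isinstance(groupA, pd.DataFrame):
        genes = groupA.index
        if isinstance(groupB, pd.DataFrame):
            groupB = groupB.loc[genes]
    A = np.asarray(groupA, dtype=float)
    B = np.asarray(groupB, dtype=float)
    nA, nB = A.shape[1], B.shape[1]
    if nA < 2 or nB < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per group")
    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA, vB = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    if prm.nu0 > 0:
        s0A = _background_variance(mA, vA, prm.window)
        s0B = _background_variance(mB, vB, prm.window)
        vrA = (prm.nu0 * s0A + (nA - 1) * vA) / (prm.nu0 + nA - 2)
        vrB = (prm.nu0 * s0B + (nB - 1) * vB) / (prm.nu0 + nB - 2)
    else:
        vrA, vrB = vA, vB
    seA = vrA / nA
    seB = vrB / nB
    denom = np.sqrt(seA + seB)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (mA - mB) / np.where(denom > 0, denom, 1.0), 0.0)
        df = np.where(
            (seA + seB) > 0,
            (seA + seB) ** 2
            / np.where(
                (seA**2 / (nA - 1) + seB**2 / (nB - 1)) > 0,
                seA**2 / (nA - 1) + seB**2 / (nB - 1),
                1.0,
            ),
            nA + nB - 2,
        ) + 2.0 * prm.nu0
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    log2_ratio = mA - mB
    out = pd.DataFrame(
        {
            "mean_a": mA,
            "mean_b": mB,
            "log2_ratio": log2_ratio,
            "fold_change": 2.0 ** np.abs(log2_ratio),
            "t_reg": t,
            "df": df,
            "p": p,
        }
    )
    if genes is not None:
        out.index = genes
    return out


def cyber_t_one_sample(
    ratios: pd.DataFrame | np.ndarray, prm: CyberTParams | None = None
) -> pd.DataFrame:
    """One-sample variant on log-ratios (null mean 0)."""
    if prm is None:
        prm = CyberTParams()
    genes = ratios.index if isinstance(ratios, pd.DataFrame) else None
    R = np.asarray(ratios, dtype=float)
    n = R.shape[1]
    if n < 2:
        raise InsufficientReplicatesError("need >= 2 replicates")
    m = R.mean(axis=1)
    v = R.var(axis=1, ddof=1)
    if prm.nu0 > 0:
        s0 = _background_variance(m, v, prm.window)
        vr = (prm.nu0 * s0 + (n - 1) * v) / (prm.nu0 + n - 2)
    else:
        vr = v
    denom = np.sqrt(vr / n)
    t = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), 0.0)
    df = (n - 1) + 2.0 * prm.nu0
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), 0.0, 1.0)
    out = pd.DataFrame(
        {
            "log2_ratio": m,
            "fold_change": 2.0 ** np.abs(m),
            "t_reg": t,
            "df": df,
            "p": p,
        }
    )
    if genes is not None:
        out.index = genes
    return out


# ---------------------------------------------------------------------------
# Significance filter


def call_significant(
    results: pd.DataFrame, ratio_min: float = 5.0, p_max: float = 1e-4
) -> list[DEResult]:
    """Apply the joint fold-change/p filter.

    ``results`` is the output of :func:`cyber_t`; a gene is significant
    iff its linear fold change (higher direction) >= ratio_min AND its
    p-value <= p_max.  A Benjamini-Hochberg column ``p_bh`` is attached
    to ``results`` as supplementary output but plays no role in the
    filter.
    """
    p = results["p"].to_numpy()
    order = np.argsort(p, kind="stable")
    n = len(p)
    bh = np.empty(n)
    ranked = p[order] * n / (np.arange(n) + 1)
    bh[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    results["p_bh"] = np.clip(bh, 0.0, 1.0)
    out = []
    for gene, row in results.iterrows():
        out.append(
            DEResult(
                gene=str(gene),
                mean_ratio=float(row["fold_change"]),
                t_reg=float(row["t_reg"]),
                p=float(row["p"]),
                significant=bool(
                    row["fold_change"] >= ratio_min and row["p"] <= p_max
                ),
            )
        )
    return out


def de_pipeline(
    probes: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    prm: CyberTParams | None = None,
    ratio_min: float = 5.0,
    p_max: float = 1e-4,
    alpha_grubbs: float = 0.05,
) -> list[DEResult]:
    """Full chain: Grubbs -> collapse -> Cyber-T -> significance filter."""
    collapsed = collapse_replicates(probes, alpha=alpha_grubbs)
    A = collapsed[condition_a]
    B = collapsed[condition_b]
    results = cyber_t(A, B, prm)
    return call_significant(results, ratio_min=ratio_min, p_max=p_max)
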