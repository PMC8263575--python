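"""Statistical layer and report assembly.

Descriptive summaries follow the normality-gated convention: samples that
pass a Shapiro-Wilk normality test (alpha 0.05) are presented as mean with
standard deviation, the rest as median with interquartile range (quartiles
by linear interpolation between order statistics). Two-group comparisons
use a pooled-variance two-tailed t test (a single-observation group is
allowed and borrows the other group's variance); multi-group comparisons
use the tie-corrected Kruskal-Wallis test. Report tables round half-up to
the printed precision.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SampleSummary",
    "shapiro_wilk",
    "ttest_two_tailed",
    "kruskal_wallis",
    "summarize_descriptive",
    "round_half_up",
    "build_table1",
    "build_table2",
    "run_manifest",
]

ALPHA = 0.05


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (0.255 -> 0.26 at 2 decimals)."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test (AS R94): returns (W, p).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample (zero variance)")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def ttest_two_tailed(sample_a, sample_b) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test, two-sided: returns (t, df, p).

    One of the groups may hold a single observation (it contributes no
    variance; df = n_a + n_b - 2 still). Both groups of size 1 is rejected.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 1 or nb < 1:
        raise ValueError("both groups must be non-empty")
    df = na + nb - 2
    if df < 1:
        raise ValueError("pooled t test needs n_a + n_b >= 3 (both groups of size 1 given)")
    ssa = ((a - a.mean()) ** 2).sum()
    ssb = ((b - b.mean()) ** 2).sum()
    sp2 = (ssa + ssb) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H test: returns (H, df, chi-square p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical: H = 0 by the ties-correction convention")
        return 0.0, df, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), df, float(p)


@dataclass
class SampleSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    normality_p: float
    mode: str  # "mean±SD" or "median(IQR)"


def summarize_descriptive(sample, alpha: float = ALPHA) -> SampleSummary:
    """Both moment and quantile summaries; presentation mode gated by normality."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    if np.ptp(x) == 0:
        # constant sample: normality test undefined; quantile presentation
        p = np.nan
        mode = "median(IQR)"
    else:
        _, p = shapiro_wilk(x)
        mode = "mean±SD" if p > alpha else "median(IQR)"
    return SampleSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        normality_p=float(p) if np.isfinite(p) else np.nan,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

#: printed precision (decimals) of each global-remodeling row
_TABLE1_ROWS = {
    "wall_thickness_mm": 1,
    "cavity_ml": 2,
    "myocardial_ml": 2,
    "mass_g": 2,
}


def build_table1(
    per_heart: dict[str, dict[str, float]], control: str | None = None
) -> pd.DataFrame:
    """Global-remodeling table: one row per metric, columns per heart plus
    the post-MI average (arithmetic mean of per-heart values, half-up at the
    printed precision) and, when a control heart is given, a two-tailed
    pooled t test of post-MI hearts against it.

    ``per_heart`` maps heart name to a metric dict with keys
    wall_thickness_mm / cavity_ml / myocardial_ml / mass_g (missing metrics
    yield NaN cells). For the thickness row a per-heart *list* of segment
    values may be supplied; its mean is the heart's value and the t test
    then compares per-heart means.
    """
    if not per_heart:
        raise ValueError("need at least one heart")
    mi_names = [h for h in per_heart if h != control]
    rows = []
    for metric, dec in _TABLE1_ROWS.items():
        row: dict[str, object] = {"metric": metric}

        def scalar(name: str) -> float:
            val = per_heart[name].get(metric, np.nan)
            return float(np.mean(val)) if np.ndim(val) else float(val)

        if control is not None:
            row["control"] = round_half_up(scalar(control), dec)
        vals = [scalar(h) for h in mi_names]
        for h, v in zip(mi_names, vals):
            row[h] = round_half_up(v, dec)
        finite = [v for v in vals if np.isfinite(v)]
        if finite:
            row["post_mi_average"] = round_half_up(float(np.mean(finite)), dec)
            row["post_mi_sd"] = (
                round_half_up(float(np.std(finite, ddof=1)), dec) if len(finite) > 1 else np.nan
            )
            if control is not None and np.isfinite(scalar(control)) and len(finite) >= 2:
                _, _, p = ttest_two_tailed(finite, [scalar(control)])
                row["p_vs_control"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def build_table2(per_heart_mdi: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Regional MDI table: median (IQR) per category per heart plus a pooled
    column over all hearts' per-segment medians.

    ``per_heart_mdi`` maps heart name to a per-*segment* MDI summary table
    (columns segment_id, category, median) as produced by
    :func:`myoarch.disarray.region_summary` with ``group_by='segment'``.
    """
    if not per_heart_mdi:
        raise ValueError("need at least one heart")
    cats = ["MI", "peri-MI", "contralateral", "remaining", "overall"]
    rows = []
    for cat in cats:
        row: dict[str, object] = {"category": cat}
        pooled: list[float] = []
        for heart, seg_df in per_heart_mdi.items():
            sub = seg_df if cat == "overall" else seg_df[seg_df["category"] == cat]
            vals = sub["median"].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[heart] = ""
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            row[heart] = f"{med:.2f} ({q1:.2f}-{q3:.2f})"
            pooled.extend(vals.tolist())
        if pooled:
            q1, med, q3 = np.percentile(pooled, [25, 50, 75])
            row["pooled"] = f"{med:.2f} ({q1:.2f}-{q3:.2f})"
        else:
            row["pooled"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def run_manifest(config: dict, outputs: dict[str, str], seed: int | None = None) -> dict:
    """Machine-readable run manifest: config hash, seed, versions, file hashes."""
    import myoarch

    cfg_text = json.dumps(config, sort_keys=True, default=str)
    files = {}
    for name, path in outputs.items():
        try:
            with open(path, "rb") as f:
                digest = hashlib.sha256(f.read()).hexdigest()
        except OSError:
            digest = None
        files[name] = {"path": str(path), "sha256": digest}
    return {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "versions": {"myoarch": myoarch.__version__, "numpy": np.__version__},
        "outputs": files,
    }
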