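"""Two-group nonparametric comparison with per-family FDR control.

Every semi-metric index is compared between the low- and high-risk groups
with the two-sided Wilcoxon rank-sum (Mann-Whitney) test, and multiplicity
is controlled *within each declared family* by Benjamini-Hochberg FDR:

* ``smr_edges``   — per-edge SMR, up to N(N-1)/2 tests (BH);
* ``smr_scales``  — global / left / right / inter SMR and the BAI, 5 tests (BH);
* ``smp_scales``  — global / left / right SMP, 3 tests (BH);
* ``smp_nodes``   — per-node SMP, N tests (BH);
* ``descriptors`` — sparsity and the four strengths, *uncorrected*;
* ``bai_vol``     — the three volumetric asymmetry networks, *uncorrected*.

The last two families are reported at plain ``p < alpha``, mirroring how
network descriptors and volumetric indices are conventionally screened as
secondary checks.  Direction is the sign of the rank-biserial correlation
(``high > low`` when the high group tends to larger values).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ConnectomeError, RegionTable

logger = logging.getLogger(__name__)

WILCOXON_MODES = ("exact", "approx", "auto")

#: Smallest group size for which the asymptotic test is preferred in auto
#: mode; below it (and without ties) the exact null distribution is used.
EXACT_MAX_N = 10

SCALE_FAMILY = ("smr_global", "smr_left", "smr_right", "smr_inter", "bai")
SMP_FAMILY = ("smp_global", "smp_left", "smp_right")
DESCRIPTOR_FAMILY = (
    "sparsity",
    "global_strength",
    "left_strength",
    "right_strength",
    "inter_strength",
)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank-sum of the first sample.
    ``auto`` uses the exact null distribution when ``min(n, m) <= 10`` and
    the pooled sample has no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise.  If every value in
    both samples is identical the test is vacuous and ``p = 1`` is returned
    by convention (logged).
    """
    if mode not in WILCOXON_MODES:
        raise ValueError(f"mode must be one of {WILCOXON_MODES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConnectomeError("both samples must be non-empty")
    n1 = x.size
    w_offset = n1 * (n1 + 1) / 2.0
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.debug("all %d pooled values identical; p = 1 by convention", pooled.size)
        ranks_sum = sps.rankdata(pooled)[:n1].sum()
        return float(ranks_sum), 1.0
    if mode == "auto":
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and no_ties) else "asymptotic"
    else:
        method = {"exact": "exact", "approx": "asymptotic"}[mode]
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    statistic = float(res.statistic + w_offset)  # U1 -> rank-sum W1
    return statistic, float(res.pvalue)


def bh_fdr(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q, reject)`` with ``q_i = min_{j: p_(j) >= p_(i)} m p_(j)/j``
    capped at 1 and ``reject = q <= alpha``.  A single p-value passes
    through unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ConnectomeError("empty p-value list")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ConnectomeError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def _direction(x: np.ndarray, y: np.ndarray) -> str:
    """Rank-biserial sign; ``x`` is the low group, ``y`` the high group."""
    u_low = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    half = x.size * y.size / 2.0
    if u_low > half:
        return "low>high"
    if u_low < half:
        return "high>low"
    return "none"


def _family_table(
    comparisons: list[tuple[str, np.ndarray, np.ndarray]],
    alpha: float,
    corrected: bool,
    mode: str = "auto",
) -> pd.DataFrame:
    rows = []
    for label, x, y in comparisons:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if x.size < 2 or y.size < 2:
            logger.info(
                "dropping comparison %r: fewer than two observations per group "
                "after missing-value removal", label,
            )
            continue
        stat, p = wilcoxon_rank_sum(x, y, mode=mode)
        rows.append(
            {
                "label": label,
                "statistic": stat,
                "p_raw": p,
                "direction": _direction(x, y),
                "n_low": x.size,
                "n_high": y.size,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df.reindex(
            columns=["label", "statistic", "p_raw", "q_bh", "significant", "direction", "n_low", "n_high"]
        )
    if corrected:
        q, reject = bh_fdr(df["p_raw"].to_numpy(), alpha=alpha)
    else:
        q, reject = df["p_raw"].to_numpy(), df["p_raw"].to_numpy() < alpha
    df["q_bh"] = q
    df["significant"] = reject
    return df[
        ["label", "statistic", "p_raw", "q_bh", "significant", "direction", "n_low", "n_high"]
    ]


def compare_groups(
    groups: pd.Series,
    summaries: pd.DataFrame,
    smp_nodes: pd.DataFrame,
    smr_stack: np.ndarray,
    regions: RegionTable,
    descriptors: pd.DataFrame | None = None,
    bai_vol: pd.DataFrame | None = None,
    alpha: float = 0.05,
    edge_presence_threshold: float = 0.5,
    mode: str = "auto",
) -> dict[str, pd.DataFrame]:
    """All family-wise group comparisons of one cohort.

    ``groups`` maps subject id to ``"low"``/``"high"``; ``summaries``,
    ``smp_nodes``, ``descriptors`` and ``bai_vol`` are subject-indexed frames
    sharing that index; ``smr_stack`` is ``(n_subjects, N, N)`` in the same
    subject order with ``NaN`` marking absent edges.

    Per-edge tests use only the subjects for whom the edge exists; edges
    present in fewer than ``edge_presence_threshold`` of either group's
    subjects are excluded (count logged) — topologically filtered networks
    are sparse and the per-edge sample would otherwise be meaningless.
    Comparisons with fewer than two observations per group are dropped with
    a log entry.
    """
    if set(groups.unique()) != {"low", "high"}:
        raise ConnectomeError("groups must contain exactly 'low' and 'high'")
    counts = groups.value_counts()
    if counts.min() < 2:
        raise ConnectomeError("need at least two subjects per group")
    order = summaries.index
    low_mask = (groups.reindex(order) == "low").to_numpy()
    high_mask = ~low_mask

    def split(frame: pd.DataFrame, col: str) -> tuple[np.ndarray, np.ndarray]:
        v = frame[col].to_numpy(dtype=float)
        return v[low_mask], v[high_mask]

    out: dict[str, pd.DataFrame] = {}

    # (a) edge scale
    edge_comparisons: list[tuple[str, np.ndarray, np.ndarray]] = []
    n_excluded = 0
    present = ~np.isnan(smr_stack)
    iu, ju = np.triu_indices(regions.n, k=1)
    frac_low = present[low_mask][:, iu, ju].mean(axis=0)
    frac_high = present[high_mask][:, iu, ju].mean(axis=0)
    ever = present[:, iu, ju].any(axis=0)
    qualify = (frac_low >= edge_presence_threshold) & (frac_high >= edge_presence_threshold)
    n_excluded = int((ever & ~qualify).sum())
    for k in np.flatnonzero(qualify):
        i, j = int(iu[k]), int(ju[k])
        col = smr_stack[:, i, j]
        x = col[low_mask & present[:, i, j]]
        y = col[high_mask & present[:, i, j]]
        if x.size < 2 or y.size < 2:
            n_excluded += 1
            continue
        label = f"{regions.names[i]}--{regions.names[j]}"
        edge_comparisons.append((label, x, y))
    if n_excluded:
        logger.info(
            "edge family: %d edges excluded by the %.0f%% presence rule",
            n_excluded,
            100 * edge_presence_threshold,
        )
    out["smr_edges"] = _family_table(edge_comparisons, alpha, corrected=True, mode=mode)

    # (b) SMR scale family and (c) SMP scale family
    out["smr_scales"] = _family_table(
        [(c, *split(summaries, c)) for c in SCALE_FAMILY], alpha, corrected=True, mode=mode
    )
    out["smp_scales"] = _family_table(
        [(c, *split(summaries, c)) for c in SMP_FAMILY], alpha, corrected=True, mode=mode
    )

    # (d) node family
    node_comparisons = [
        (str(col), *split(smp_nodes, col)) for col in smp_nodes.columns
    ]
    out["smp_nodes"] = _family_table(node_comparisons, alpha, corrected=True, mode=mode)

    # (e) descriptors, uncorrected
    if descriptors is not None:
        out["descriptors"] = _family_table(
            [(c, *split(descriptors, c)) for c in DESCRIPTOR_FAMILY],
            alpha,
            corrected=False,
            mode=mode,
        )

    # (f) volumetric asymmetry, uncorrected
    if bai_vol is not None:
        out["bai_vol"] = _family_table(
            [(str(c), *split(bai_vol, c)) for c in bai_vol.columns],
            alpha,
            corrected=False,
            mode=mode,
        )
    return out


def rejection_counts(families: Mapping[str, pd.DataFrame]) -> dict[str, dict[str, int]]:
    """Per-family number of comparisons and rejections (for run reports)."""
    return {
        fid: {
            "n_comparisons": int(len(df)),
            "n_significant": int(df["significant"].sum()) if len(df) else 0,
        }
        for fid, df in families.items()
    }
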