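"""One-way ANOVA comparisons of network features and per-edge PLI.

Conditions are compared as independent groups with a classical one-way
ANOVA (F on k − 1, N − k degrees of freedom).  Two comparisons are
provided: per (band, metric) on AUC network features, and per edge on
window-averaged PLI values, the latter retaining edges with p < alpha
(uncorrected by default; an FDR option exists but is off, matching the
plain p < 0.05 screen that precedes SVM-RFE ranking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import Montage
from .network import METRICS, NetworkFeatureProfile


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA: returns (F, p).

    Degenerate zero-variance input is defined rather than NaN: identical
    groups give (0, 1); zero within-group variance with distinct means
    gives (inf, 0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(g.ndim != 1 or g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    n_total = ns.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        return (0.0, 1.0) if ss_between == 0.0 else (float("inf"), 0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, float(sps.f.sf(f, df_b, df_w))


def _anova_two_group_vectorized(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group one-way ANOVA over the last-but-one axis, per feature.

    ``a``, ``b``: (n_subjects, n_features).  Returns (F, p) arrays of
    length n_features; degenerate features follow :func:`anova_oneway`.
    """
    na, nb = a.shape[0], b.shape[0]
    grand = (a.sum(axis=0) + b.sum(axis=0)) / (na + nb)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ssw = ((a - ma) ** 2).sum(axis=0) + ((b - mb) ** 2).sum(axis=0)
    df_w = na + nb - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ssw > 0, ssb / (ssw / df_w), np.where(ssb > 0, np.inf, 0.0))
    p = np.where(
        np.isinf(f), 0.0, np.where(ssw > 0, sps.f.sf(np.where(ssw > 0, f, 0.0), 1, df_w), 1.0)
    )
    return f, p


@dataclass(frozen=True)
class GroupComparison:
    feature: tuple[str, str]  # (band, metric) or (band, "chA-chB")
    f: float
    p: float
    means: tuple[float, float]
    sds: tuple[float, float]


def compare_network_features(
    profiles: dict[str, dict[str, list[NetworkFeatureProfile]]],
) -> pd.DataFrame:
    """ANOVA of AUC network features between two conditions.

    ``profiles[condition][band]`` is the per-subject list of
    :class:`NetworkFeatureProfile`.  Returns a tidy frame with one row
    per (band, metric): F, p, per-condition mean and SD of the AUC.
    """
    conds = sorted(profiles)
    if len(conds) != 2:
        raise ValueError("exactly two conditions expected")
    c0, c1 = conds
    if set(profiles[c0]) != set(profiles[c1]):
        raise ValueError("conditions must cover the same bands")
    rows = []
    for band in profiles[c0]:
        g0_list, g1_list = profiles[c0][band], profiles[c1][band]
        if len(g0_list) != len(g1_list):
            raise ValueError("conditions must have equal subject counts")
        for metric in METRICS:
            g0 = np.array([pr.auc[metric] for pr in g0_list])
            g1 = np.array([pr.auc[metric] for pr in g1_list])
            f, p = anova_oneway([g0, g1])
            rows.append(
                dict(band=band, metric=metric, F=f, p=p,
                     mean_0=g0.mean(), mean_1=g1.mean(),
                     sd_0=g0.std(ddof=1), sd_1=g1.std(ddof=1),
                     condition_0=c0, condition_1=c1)
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SignificantEdgeSet:
    """Edges of one band whose PLI differs between conditions at p < alpha."""

    band: str
    alpha: float
    edges: tuple[tuple[int, int], ...]  # channel index pairs, i < j
    f: np.ndarray
    p: np.ndarray


def select_significant_edges(
    mean_conn: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
    fdr: bool = False,
) -> dict[str, SignificantEdgeSet]:
    """Per band, ANOVA across all edges; keep those with p < alpha.

    ``mean_conn[condition][band]`` is an (n_subjects, C, C) stack of
    window-averaged PLI matrices.  ``fdr=True`` applies a
    Benjamini–Hochberg correction before the alpha cut (off by default).
    """
    conds = sorted(mean_conn)
    if len(conds) != 2:
        raise ValueError("exactly two conditions expected")
    out: dict[str, SignificantEdgeSet] = {}
    for band in mean_conn[conds[0]]:
        stacks = [np.asarray(mean_conn[c][band]) for c in conds]
        n_ch = stacks[0].shape[1]
        iu, ju = np.triu_indices(n_ch, k=1)
        a = stacks[0][:, iu, ju]
        b = stacks[1][:, iu, ju]
        f, p = _anova_two_group_vectorized(a, b)
        p_eff = _bh_adjust(p) if fdr else p
        keep = np.flatnonzero(p_eff < alpha)
        out[band] = SignificantEdgeSet(
            band=band, alpha=alpha,
            edges=tuple((int(iu[k]), int(ju[k])) for k in keep),
            f=f[keep], p=p_eff[keep],
        )
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p values."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def comparisons_to_frame(edge_sets: dict[str, SignificantEdgeSet],
                         montage: Montage) -> pd.DataFrame:
    """Tidy export of significant edges with channel labels."""
    rows = []
    for band, es in edge_sets.items():
        for (i, j), f, p in zip(es.edges, es.f, es.p):
            rows.append(
                dict(band=band, channel_a=montage.labels[i],
                     channel_b=montage.labels[j], F=f, p=p)
            )
    return pd.DataFrame(rows, columns=["band", "channel_a", "channel_b", "F", "p"])
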