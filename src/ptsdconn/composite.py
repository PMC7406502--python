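"""Composite connectivity metrics, network-pair summaries and group tests.

Once the subnetwork associated with treatment improvement is identified,
it is summarised two ways: a single composite metric (the unweighted mean
Fisher z over all its edges, per subject) and per network-pair means
(edges grouped by the unordered pair of intrinsic-network labels of their
endpoints).  The edge-count-weighted average of the pair means equals the
composite exactly.

Group comparisons follow the study design: one-way ANOVA for PTSD vs
control at baseline, pairwise contrasts after splitting patients into
responders and nonresponders, and a mixed between-within (group x time)
ANOVA across sessions with post hoc contrasts, all BH-FDR adjusted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import ParcelAtlas
from .connectivity import Connectome
from .errors import FormatError, InputError

logger = logging.getLogger(__name__)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection flags).

    Adjusted p values are monotone nondecreasing in raw-p rank;
    rejections are ``adjusted <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p values must lie in (0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def _normalize_edges(edge_set, n_nodes: int) -> list[tuple[int, int]]:
    edges = []
    for a, b in edge_set:
        a, b = int(a), int(b)
        if not (0 <= a < n_nodes and 0 <= b < n_nodes) or a == b:
            raise FormatError(f"edge ({a}, {b}) invalid for {n_nodes} nodes")
        edges.append((a, b) if a < b else (b, a))
    return sorted(set(edges))


def composite_metric(connectomes: list[Connectome], edge_set) -> np.ndarray:
    """Per-subject unweighted mean Fisher z over the edge set."""
    if not edge_set:
        raise InputError("edge_set is empty")
    n_nodes = connectomes[0].z_matrix.shape[0]
    edges = _normalize_edges(edge_set, n_nodes)
    rows = np.array([e[0] for e in edges])
    cols = np.array([e[1] for e in edges])
    return np.array([c.z_matrix[rows, cols].mean() for c in connectomes])


@dataclass
class NetworkPairSummary:
    """Mean z per subject for one unordered pair of intrinsic networks."""

    pair: tuple[str, str]
    edge_count: int
    mean_z: np.ndarray  # per subject, in input order


def network_pair_means(
    connectomes: list[Connectome],
    atlas: ParcelAtlas,
    edge_set,
) -> list[NetworkPairSummary]:
    """Group the significant edges by endpoint-network pair and average.

    Every edge maps to exactly one unordered pair, so the edge counts sum
    to ``len(edge_set)`` and the count-weighted mean over pairs
    reproduces :func:`composite_metric`.
    """
    edges = _normalize_edges(edge_set, atlas.n_nodes)
    nets = atlas.networks
    by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for i, j in edges:
        pair = tuple(sorted((nets[i], nets[j])))
        by_pair.setdefault(pair, []).append((i, j))
    out = []
    for pair in sorted(by_pair):
        pe = by_pair[pair]
        rows = np.array([e[0] for e in pe])
        cols = np.array([e[1] for e in pe])
        mean_z = np.array([c.z_matrix[rows, cols].mean() for c in connectomes])
        out.append(NetworkPairSummary(pair=pair, edge_count=len(pe), mean_z=mean_z))
    return out


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def baseline_group_tests(
    values: np.ndarray,
    groups,
    measure: str = "composite",
) -> pd.DataFrame:
    """Baseline comparisons of one measure across response groups.

    Returns a tidy table with the PTSD-vs-control one-way ANOVA and the
    Welch pairwise contrasts responder-vs-control, nonresponder-vs-control
    and responder-vs-nonresponder.  Groups with fewer than 2 members have
    their contrasts skipped (logged).  BH-FDR adjustment across a set of
    measures is applied afterwards with :func:`fdr_adjust_table`.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    sel = {
        g: values[groups == g] for g in ("responder", "nonresponder", "control")
    }
    patients = np.concatenate([sel["responder"], sel["nonresponder"]])
    rows = []
    if len(patients) >= 2 and len(sel["control"]) >= 2:
        f, p = stats.f_oneway(patients, sel["control"])
        rows.append(
            dict(measure=measure, contrast="ptsd_vs_control",
                 estimate=float(patients.mean() - sel["control"].mean()),
                 statistic=float(f), p=float(p), kind="anova_F")
        )
    for ga, gb in (
        ("responder", "control"),
        ("nonresponder", "control"),
        ("responder", "nonresponder"),
    ):
        if len(sel[ga]) < 2 or len(sel[gb]) < 2:
            logger.warning("contrast %s vs %s skipped: group too small", ga, gb)
            continue
        t, p = _welch(sel[ga], sel[gb])
        rows.append(
            dict(measure=measure, contrast=f"{ga}_vs_{gb}",
                 estimate=float(sel[ga].mean() - sel[gb].mean()),
                 statistic=t, p=p, kind="welch_t")
        )
    return pd.DataFrame(
        rows, columns=["measure", "contrast", "estimate", "statistic", "p", "kind"]
    )


def fdr_adjust_table(table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Append BH-FDR adjusted p and rejection flags to a tidy test table."""
    out = table.copy()
    if len(out) == 0:
        out["p_fdr"] = []
        out["significant_fdr"] = []
        return out
    adj, rej = bh_fdr(out["p"].to_numpy(), q=q)
    out["p_fdr"] = adj
    out["significant_fdr"] = rej
    return out


def group_by_time_anova(
    values_pre: np.ndarray,
    values_post: np.ndarray,
    groups,
    alpha: float = 0.05,
    measure: str = "composite",
) -> dict:
    """Mixed between-within ANOVA (group x time) with post hoc contrasts.

    Subjects missing the post value are excluded listwise (logged),
    mirroring follow-up attrition.  If the interaction is significant at
    ``alpha``, paired pre-vs-post t tests per group and Welch between-group
    contrasts at each time are run and BH-FDR adjusted.  With a single
    group the ANOVA degenerates to the paired t test on time.
    """
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    groups = np.asarray(groups, dtype=object)
    ok = np.isfinite(pre) & np.isfinite(post)
    if (~ok).any():
        logger.warning("excluding %d subjects without both sessions", int((~ok).sum()))
    pre, post, groups = pre[ok], post[ok], groups[ok]
    labels = [g for g in ("responder", "nonresponder", "control", *np.unique(groups))
              if g in set(groups)]
    labels = list(dict.fromkeys(labels))

    if np.array_equal(pre, post):
        # no change anywhere: time and interaction effects are null by
        # definition (the F ratios are 0/0); report them as absent
        anova = pd.DataFrame(
            [dict(Source="time", F=0.0, p=1.0),
             dict(Source="Interaction", F=0.0, p=1.0)]
        )
        interaction_p = 1.0
    elif len(labels) == 1:
        t, p = stats.ttest_rel(post, pre)
        anova = pd.DataFrame(
            [dict(Source="time", F=float(t**2), p=float(p))]
        )
        interaction_p = np.nan
    else:
        n = len(pre)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(n), 2),
                "time": np.repeat(["pre", "post"], n),
                "group": np.tile(groups, 2),
                "value": np.concatenate([pre, post]),
            }
        )
        anova = pg.mixed_anova(
            data=long, dv="value", within="time", subject="subject", between="group"
        )
        anova = anova.rename(columns={"p_unc": "p", "p-unc": "p"})
        interaction_p = float(
            anova.loc[anova["Source"] == "Interaction", "p"].iloc[0]
        )

    posthoc_rows = []
    if len(labels) > 1 and np.isfinite(interaction_p) and interaction_p < alpha:
        for g in labels:
            gi = groups == g
            t, p = stats.ttest_rel(post[gi], pre[gi])
            posthoc_rows.append(
                dict(measure=measure, contrast=f"{g}_post_vs_pre",
                     estimate=float(post[gi].mean() - pre[gi].mean()),
                     statistic=float(t), p=float(p), kind="paired_t")
            )
        for (ga, gb), tp in itertools.product(
            itertools.combinations(labels, 2), ("pre", "post")
        ):
            va = pre if tp == "pre" else post
            t, p = _welch(va[groups == ga], va[groups == gb])
            posthoc_rows.append(
                dict(measure=measure, contrast=f"{ga}_vs_{gb}_{tp}",
                     estimate=float(va[groups == ga].mean() - va[groups == gb].mean()),
                     statistic=t, p=p, kind="welch_t")
            )
    posthoc = fdr_adjust_table(pd.DataFrame(posthoc_rows))

    return {
        "anova": anova,
        "interaction_p": interaction_p,
        "posthoc": posthoc,
        "n_included": len(pre),
    }


def partial_correlation_retest(
    composite: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray,
) -> dict:
    """Association of composite with improvement, controlling covariates.

    Partial Pearson correlation: both variables are residualised on the
    covariates (with intercept) and the residuals correlated, with p from
    the t transform on n - 2 - k df.
    """
    x = np.asarray(composite, dtype=float)
    y = np.asarray(outcome, dtype=float)
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != x.shape[0]:
        c = c.T
    n, k = c.shape
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"r_partial": r, "p": float(p), "df": df, "n": n}
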