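"""Synthetic cohorts with known ground truth for every pipeline stage.

Two generators share one :class:`SimulationConfig`:

* :func:`simulate_cohort_connectomes` draws per-subject Fisher-z
  connectomes directly, with a planted edge subnetwork whose baseline
  connectivity is linearly related to treatment improvement (negative
  direction by default: lower connectivity, greater improvement), plus a
  clinical table with CAPS totals, covariates and responder labels, and a
  pre-to-post shift of the planted edges toward the control mean for
  patients.
* :func:`simulate_timeseries_cohort` draws per-run parcel time series
  from latent network factors plus AR(1) node noise, contaminated with
  task covariates, slow drift, tissue signals and motion spikes, as raw
  input for the intrinsic-connectivity stage.

All randomness flows from ``config.seed`` through one generator, so
identical configs give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import ParcelAtlas, make_atlas
from .clinical import derive_outcomes
from .connectivity import Connectome, SubjectRunTimeSeries
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

# --- fixed generator constants (documented in the methods note) ---------
#: SD of the per-subject deviation shared by all planted edges (z units).
PLANTED_SUBJECT_SD = 0.25
#: SD of independent per-edge, per-subject measurement noise (z units).
EDGE_NOISE_SD = 0.08
#: SD of a per-subject global connectivity offset (z units).
SUBJECT_OFFSET_SD = 0.03
#: Baseline CAPS: Normal(72, 14) truncated to [45, 120].
CAPS_MEAN, CAPS_SD, CAPS_LO, CAPS_HI = 72.0, 14.0, 45.0, 120.0

#: Networks used by the desk-scale default atlas.
SIM_NETWORKS = (
    "default_mode",
    "frontoparietal",
    "cingulo_opercular",
    "salience",
    "dorsal_attention",
    "ventral_attention",
    "auditory",
    "visual",
)
#: Networks the planted subnetwork is drawn from (the implicated systems).
PLANTED_NETWORKS = (
    "cingulo_opercular",
    "salience",
    "default_mode",
    "dorsal_attention",
    "frontoparietal",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    Defaults are the study conditions: 36 patients and 36 controls, a
    25/36 responder fraction, five runs of 120 frames at TR 2.5 s, and a
    negative link between planted-edge connectivity and improvement.
    ``n_nodes`` defaults to the 40-node desk scale used throughout the
    simulation-based checks.
    """

    n_nodes: int = 40
    network_names: tuple[str, ...] = SIM_NETWORKS
    n_patients: int = 36
    n_controls: int = 36
    n_timepoints_per_run: int = 120
    n_runs: int = 5
    tr_seconds: float = 2.5
    ar_coefficient: float = 0.3
    within_network_coupling: float = 0.3
    between_network_coupling: float = 0.1
    planted_edges: frozenset[tuple[int, int]] | None = None
    n_planted_edges: int = 15
    effect_size: float = 0.8
    noise_sd: float = 0.05
    responder_fraction: float = 25.0 / 36.0
    group_time_shift: float = 0.8
    motion_spike_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < len(self.network_names):
            raise ConfigurationError("need at least one node per network")
        for name in ("n_patients", "n_controls", "n_timepoints_per_run", "n_runs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 <= self.ar_coefficient < 1):
            raise ConfigurationError("ar_coefficient must be in [0, 1)")
        if not (0 < self.responder_fraction < 1):
            raise ConfigurationError("responder_fraction must be in (0, 1)")
        if not (0 <= self.motion_spike_rate < 1):
            raise ConfigurationError("motion_spike_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for name in ("within_network_coupling", "between_network_coupling"):
            if not (-1 <= getattr(self, name) <= 1):
                raise ConfigurationError(f"{name} must be in [-1, 1]")
        if self.planted_edges is not None:
            for a, b in self.planted_edges:
                if a == b or not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                    raise ConfigurationError(f"invalid planted edge ({a}, {b})")

    def atlas(self) -> ParcelAtlas:
        """Deterministic atlas implied by the config (seeded block sizes)."""
        return make_atlas(self.n_nodes, [], self.network_names, seed=self.seed)


def default_planted_edges(
    atlas: ParcelAtlas, n_edges: int, seed: int
) -> frozenset[tuple[int, int]]:
    """A connected planted subnetwork among the implicated networks.

    Edges are grown from a seeded random tree over candidate nodes (so
    the planted subnetwork is one connected component, as the component
    statistic assumes) and topped up with extra random pairs among the
    already-included nodes.
    """
    rng = np.random.default_rng(seed)
    candidates = np.flatnonzero(np.isin(atlas.networks, PLANTED_NETWORKS))
    if len(candidates) < 3:
        candidates = np.arange(atlas.n_nodes)
    edges: set[tuple[int, int]] = set()
    included = [int(rng.choice(candidates))]
    while len(edges) < n_edges:
        if len(included) < len(candidates) and (len(edges) < len(candidates) - 1):
            # tree growth: connect a new node to an included one
            rest = [c for c in candidates if c not in included]
            new = int(rng.choice(rest))
            old = int(rng.choice(included))
            included.append(new)
            e = (min(new, old), max(new, old))
        else:
            a, b = rng.choice(included, size=2, replace=False)
            e = (min(int(a), int(b)), max(int(a), int(b)))
        edges.add(e)
    return frozenset(edges)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return mean + sd * stats.norm.ppf(u)


def _edge_upper(n_nodes):
    return np.triu_indices(n_nodes, k=1)


def _to_matrix(edge_values: np.ndarray, n_nodes: int) -> np.ndarray:
    z = np.zeros((n_nodes, n_nodes))
    iu, ju = _edge_upper(n_nodes)
    z[iu, ju] = edge_values
    return z + z.T


def simulate_cohort_connectomes(
    config: SimulationConfig,
) -> tuple[list[Connectome], pd.DataFrame, frozenset[tuple[int, int]]]:
    """Draw baseline and post connectomes plus the clinical table.

    Patients' improvement fraction is
    ``intercept - effect_size * (planted mean z - its expectation) + noise``
    with the intercept set so the expected responder rate equals
    ``responder_fraction``; CAPS post is derived from the improvement
    and clipped to [0, 120] (with a logged warning when clipping bites).
    At the post session patients' planted-edge deviations shrink by
    ``group_time_shift`` toward the control mean; controls get fresh
    measurement noise only.
    """
    rng = np.random.default_rng(config.seed)
    atlas = config.atlas()
    n_nodes = atlas.n_nodes
    iu, ju = _edge_upper(n_nodes)
    n_edges = len(iu)
    nets = atlas.networks

    planted = config.planted_edges
    if planted is None:
        planted = default_planted_edges(atlas, config.n_planted_edges, config.seed)
    planted_mask = np.zeros(n_edges, dtype=bool)
    for k, (i, j) in enumerate(zip(iu, ju)):
        if (min(i, j), max(i, j)) in planted or (i, j) in planted:
            planted_mask[k] = True
    n_planted = int(planted_mask.sum())

    same_net = nets[iu] == nets[ju]
    base = np.where(same_net, config.within_network_coupling,
                    config.between_network_coupling)

    n_pat, n_ctl = config.n_patients, config.n_controls
    n_sub = n_pat + n_ctl
    subject_ids = [f"sub-{k + 1:03d}" for k in range(n_sub)]
    groups = ["patient"] * n_pat + ["control"] * n_ctl

    offsets = rng.normal(0.0, SUBJECT_OFFSET_SD, size=n_sub)
    deltas = rng.normal(0.0, PLANTED_SUBJECT_SD, size=n_sub)
    noise_pre = rng.normal(0.0, EDGE_NOISE_SD, size=(n_sub, n_edges))
    noise_post = rng.normal(0.0, EDGE_NOISE_SD, size=(n_sub, n_edges))

    edges_pre = base + offsets[:, None] + noise_pre
    edges_pre[:, planted_mask] += deltas[:, None]

    # improvement linked to the realised planted-edge mean at baseline
    m = edges_pre[:, planted_mask].mean(axis=1)
    m_expected = float(base[planted_mask].mean())
    var_m = PLANTED_SUBJECT_SD**2 + SUBJECT_OFFSET_SD**2 + EDGE_NOISE_SD**2 / n_planted
    sigma_tot = np.sqrt(config.effect_size**2 * var_m + config.noise_sd**2)
    intercept = 0.5 - sigma_tot * stats.norm.ppf(1.0 - config.responder_fraction)
    improvement = (
        intercept
        - config.effect_size * (m - m_expected)
        + rng.normal(0.0, config.noise_sd, size=n_sub)
    )

    caps_pre = _truncnorm(rng, CAPS_MEAN, CAPS_SD, CAPS_LO, CAPS_HI, n_sub)
    caps_post_raw = caps_pre * (1.0 - improvement)
    clipped = (caps_post_raw < 0) | (caps_post_raw > CAPS_HI)
    if clipped[:n_pat].any():
        logger.warning(
            "post CAPS clipped to [0, %g] for %d patients",
            CAPS_HI, int(clipped[:n_pat].sum()),
        )
    caps_post = np.clip(caps_post_raw, 0.0, CAPS_HI)

    # post-session deviations shrink toward the control mean for patients
    deltas_post = deltas.copy()
    deltas_post[:n_pat] = deltas[:n_pat] * (1.0 - config.group_time_shift)
    edges_post = base + offsets[:, None] + noise_post
    edges_post[:, planted_mask] += deltas_post[:, None]

    connectomes: list[Connectome] = []
    for s in range(n_sub):
        for session, ev in (("baseline", edges_pre[s]), ("post", edges_post[s])):
            connectomes.append(
                Connectome(
                    subject_id=subject_ids[s],
                    session=session,
                    z_matrix=_to_matrix(ev, n_nodes),
                    atlas_id=atlas.atlas_id,
                    n_retained_frames=config.n_runs * config.n_timepoints_per_run,
                )
            )

    is_pat = np.array([g == "patient" for g in groups])
    cohort = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": groups,
            "caps_pre": np.where(is_pat, caps_pre, np.nan),
            "caps_post": np.where(is_pat, caps_post, np.nan),
            "age": np.clip(rng.normal(39.7, 11.3, n_sub), 18, 70).round(1),
            "sex": rng.choice(["f", "m"], size=n_sub),
            "dass_depression": np.clip(rng.normal(10.9, 5.5, n_sub), 0, None).round(1),
            "dass_anxiety": np.clip(rng.normal(8.1, 4.4, n_sub), 0, None).round(1),
            "dass_stress": np.clip(rng.normal(12.0, 4.4, n_sub), 0, None).round(1),
            "ssri": rng.random(n_sub) < 0.278,
            "mdd": rng.random(n_sub) < 0.528,
            "gad": rng.random(n_sub) < 0.333,
        }
    )
    cohort.loc[~is_pat, ["ssri", "mdd", "gad"]] = False  # healthy controls
    cohort = derive_outcomes(cohort)
    return connectomes, cohort, frozenset(planted)


def simulate_timeseries_cohort(
    config: SimulationConfig,
    sessions: tuple[str, ...] = ("baseline",),
) -> list[SubjectRunTimeSeries]:
    """Per-run parcel time series from a latent network factor model.

    Node ``i`` follows ``sqrt(w - b) * f_net(i) + sqrt(b) * g + e_i`` with
    AR(1) node noise, then gains task-covariate contamination, slow
    drift, tissue-signal leakage and motion spikes: at spiked frames the
    signal and one motion parameter take a persistent step, so framewise
    displacement and DVARS are large exactly at those frames.
    """
    w, b = config.within_network_coupling, config.between_network_coupling
    if w < 0 or b < 0 or w < b:
        raise ConfigurationError(
            "time-series generation needs 0 <= between <= within coupling"
        )
    t_len = config.n_timepoints_per_run
    if t_len < 27:  # 3 x the band-pass filter length at 4th order
        raise ConfigurationError("n_timepoints_per_run too short for filtering")
    rng = np.random.default_rng(config.seed)
    atlas = config.atlas()
    nets = atlas.networks
    net_index = {name: k for k, name in enumerate(dict.fromkeys(nets))}
    node_net = np.array([net_index[x] for x in nets])
    n_nodes, n_net = atlas.n_nodes, len(net_index)

    def ar1(shape, coef):
        innov = rng.normal(size=shape)
        if coef == 0:
            return innov
        out = np.empty(shape)
        out[..., 0] = innov[..., 0] / np.sqrt(1 - coef**2)
        for t in range(1, shape[-1]):
            out[..., t] = coef * out[..., t - 1] + innov[..., t]
        return out * np.sqrt(1 - coef**2)

    runs: list[SubjectRunTimeSeries] = []
    n_sub = config.n_patients + config.n_controls
    for s in range(n_sub):
        sid = f"sub-{s + 1:03d}"
        for session in sessions:
            for r in range(config.n_runs):
                factors = ar1((n_net, t_len), 0.3)
                global_f = ar1((t_len,), 0.3)
                noise = ar1((n_nodes, t_len), config.ar_coefficient)
                data = (
                    np.sqrt(max(w - b, 0.0)) * factors[node_net]
                    + np.sqrt(max(b, 0.0)) * global_f
                    + noise
                )

                # task covariates: two boxcars with jitter
                period = max(8, t_len // 6)
                tt = np.arange(t_len)
                task = np.vstack(
                    [
                        ((tt + rng.integers(period)) // (period // 2)) % 2,
                        ((tt + rng.integers(period)) // (period // 2 + 2)) % 2,
                    ]
                ).astype(float)
                betas = rng.normal(0.0, 0.7, size=(n_nodes, task.shape[0]))
                data = data + betas @ task

                # slow drift: linear + low-frequency sine (below the band)
                drift = np.vstack(
                    [
                        np.linspace(-1, 1, t_len),
                        np.sin(2 * np.pi * 0.003 * tt * config.tr_seconds),
                    ]
                )
                data = data + rng.normal(0.0, 0.5, size=(n_nodes, 2)) @ drift

                # tissue signals leaking into node series
                tissue = ar1((2, t_len), 0.5)
                data = data + rng.normal(0.0, 0.3, size=(n_nodes, 2)) @ tissue

                # motion: slow random walk + persistent spikes
                trans = np.cumsum(rng.normal(0, 0.02, size=(3, t_len)), axis=1)
                rot = np.cumsum(rng.normal(0, 2e-4, size=(3, t_len)), axis=1)
                spikes = np.flatnonzero(
                    rng.random(t_len) < config.motion_spike_rate
                )
                spikes = spikes[spikes > 0]
                for fr in spikes:
                    axis = rng.integers(3)
                    trans[axis, fr:] += 0.8 * rng.choice([-1.0, 1.0])
                    data[:, fr:] += rng.normal(0.0, 3.0, size=(n_nodes, 1))
                motion = np.vstack([trans, rot])
                fd = np.concatenate(
                    (
                        [0.0],
                        np.abs(np.diff(trans, axis=1)).sum(axis=0)
                        + 50.0 * np.abs(np.diff(rot, axis=1)).sum(axis=0),
                    )
                )
                runs.append(
                    SubjectRunTimeSeries(
                        subject_id=sid,
                        session=session,
                        run_id=f"run-{r + 1}",
                        data=data,
                        tr_seconds=config.tr_seconds,
                        motion_params=motion,
                        task_covariates=task,
                        nuisance_signals=tissue,
                        fd_trace=fd,
                    )
                )
    return runs
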