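"""Synthetic cohorts with planted modular structure and planted effects.

Every downstream stage of the pipeline is testable without external imaging
data by generating, per subject:

* a (volumes x nodes) BOLD-like time-series matrix drawn from a zero-mean
  multivariate normal whose correlation matrix is block-constant —
  ``within_corr`` inside planted modules, ``between_corr`` elsewhere — so
  the modular signal that modularity, participation and within-module
  degree measure is under direct control;
* a 6-column rigid-body motion trace whose framewise displacement averages
  a controllable target;
* a phenotype row: a right-skewed symptom index (gamma-shaped base score
  matched to the 0-28 raw-score range of an adult ADHD rating scale, with
  mean ~8.4 and SD ~5.1), four subscales, and the covariates age, sex,
  handedness and full-scale IQ.

A planted brain-behavior effect is realized through a per-subject latent
trait u_s that raises the effect nodes' between-module correlation; the
symptom index is then built so that its partial correlation (given the
covariates) with a supplied per-subject regional metric ("nodal truth",
normally the measured mean participation of the effect nodes) equals
``effect_size``.

Node coordinates lie on a 3-D lattice (default spacing 12 mm) so the
< 20-mm distance exclusion removes nearest-neighbour and face-diagonal
pairs, emulating the short-range edge pruning applied to real data.

One global seed expands into per-subject child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stream, subject))`` with fixed
stream codes, so cohorts are reproducible even under subject-level
parallelism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cartography, community, graphs, motion

# seed-splitting stream codes
_STREAM_TIMESERIES = 0
_STREAM_MOTION = 1
_STREAM_PHENOTYPE = 2
_STREAM_LATENT = 3

#: symptom-index base distribution (gamma), matched to raw-score M ~8.36, SD ~5.13
ADHD_BASE_MEAN = 8.36
ADHD_BASE_SD = 5.13
ADHD_MAX = 28.0

#: subscale (mean, sd) targets on the raw-score scale
SUBSCALES = {
    "inattention": (3.82, 3.83),
    "hyperactivity": (4.42, 2.65),
    "impulsivity": (3.07, 2.32),
    "self_concept_problems": (4.24, 3.22),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative conditions for one synthetic cohort.

    ``effect_modulation`` scales how strongly the latent trait perturbs the
    effect nodes' between-module correlation (SD of the perturbation).
    """

    n_subjects: int = 100
    n_nodes: int = 200
    n_volumes: int = 150
    module_sizes: tuple[int, ...] = (50, 50, 50, 50)
    within_corr: float = 0.3
    between_corr: float = 0.05
    effect_nodes: tuple[int, ...] = ()
    effect_size: float = 0.0
    fd_mean: float = 0.1
    fd_sd: float = 0.04
    seed: int = 0
    lattice_spacing: float = 12.0
    effect_modulation: float = 0.10

    def __post_init__(self):
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)}, "
                f"expected n_nodes={self.n_nodes}"
            )
        if not (abs(self.between_corr) <= self.within_corr < 1):
            raise ValueError(
                "need |between_corr| <= within_corr < 1 for a valid block model"
            )
        if not (-1 < self.effect_size < 1):
            raise ValueError("effect_size must lie in (-1, 1)")
        if self.fd_mean < 0 or self.fd_sd < 0:
            raise ValueError("fd_mean and fd_sd must be non-negative")
        if self.effect_nodes and (
            min(self.effect_nodes) < 0 or max(self.effect_nodes) >= self.n_nodes
        ):
            raise ValueError("effect_nodes outside the node range")
        # positive semi-definiteness of the implied block correlation
        eig = np.linalg.eigvalsh(block_correlation(self))
        if eig.min() < -1e-10:
            raise ValueError(
                f"block specification is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g})"
            )


@dataclass
class Cohort:
    """In-memory synthetic cohort: the inputs every pipeline stage consumes."""

    spec: CohortSpec
    timeseries: list[np.ndarray]        # per subject, (n_volumes, n_nodes)
    motion_traces: list[np.ndarray]     # per subject, (n_volumes, 6)
    phenotypes: pd.DataFrame
    coordinates: pd.DataFrame           # node_id, x, y, z (mm)
    nodal_truth: np.ndarray | None      # per-subject regional metric
    latent: np.ndarray | None           # per-subject latent trait u_s

    @property
    def subject_ids(self) -> list[str]:
        return list(self.phenotypes["subject_id"])


def child_seed(seed: int, stream: int, subject: int) -> np.random.SeedSequence:
    """Documented seed-splitting rule: (global seed, stream code, subject index)."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream), int(subject)))


def module_labels(spec: CohortSpec) -> np.ndarray:
    """Planted module assignment, 1..m, contiguous blocks of node indices."""
    return np.repeat(np.arange(1, len(spec.module_sizes) + 1), spec.module_sizes)


def block_correlation(spec: CohortSpec) -> np.ndarray:
    """The generating block-constant correlation matrix (diagonal 1)."""
    lab = module_labels(spec)
    r = np.where(lab[:, None] == lab[None, :], spec.within_corr, spec.between_corr)
    np.fill_diagonal(r, 1.0)
    return r


def _nearest_correlation(r: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped projection back to a valid correlation matrix."""
    w, v = np.linalg.eigh(r)
    if w.min() >= 1e-10:
        return r
    w = np.clip(w, 1e-10, None)
    r2 = (v * w) @ v.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    np.fill_diagonal(r2, 1.0)
    return r2


def generate_modular_timeseries(
    spec: CohortSpec,
    subject_seed,
    between_boost: float = 0.0,
) -> np.ndarray:
    """One subject's (volumes x nodes) matrix from the planted block model.

    ``between_boost`` adds a constant to the correlation between the spec's
    effect nodes and all nodes of *other* modules (the planted-effect
    mechanism); the perturbed matrix is projected back to a valid
    correlation matrix if the shift breaks positive semi-definiteness.
    Deterministic given the seeds.
    """
    r = block_correlation(spec)
    if between_boost != 0.0:
        if not spec.effect_nodes:
            raise ValueError("between_boost requires effect_nodes in the spec")
        lab = module_labels(spec)
        eff = np.array(spec.effect_nodes, dtype=int)
        other = lab[:, None] != lab[None, :]
        mask = np.zeros_like(other)
        mask[eff, :] = True
        mask[:, eff] = True
        mask &= other
        r = np.clip(r + between_boost * mask, -0.95, 0.95)
        np.fill_diagonal(r, 1.0)
        r = _nearest_correlation(r)
    # Cholesky with a tiny jitter guard for semidefinite corner cases
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(r + 1e-8 * np.eye(r.shape[0]))
    rng = np.random.default_rng(subject_seed)
    white = rng.standard_normal((spec.n_volumes, spec.n_nodes))
    return white @ chol.T


def generate_motion_trace(
    n_volumes: int, fd_mean: float, fd_sd: float, seed
) -> np.ndarray:
    """A 6-column rigid-body trace whose mean FD targets ``fd_mean``.

    Per-volume FD magnitudes are drawn from a gamma distribution with mean
    ``fd_mean * n / (n - 1)`` (the first volume's FD is 0 by convention and
    included in the mean) and SD ``fd_sd``, then split across the six
    parameters with random Dirichlet weights and signs.  For
    ``n_volumes >= 100`` the realized mean FD is within 10 % of the target
    with high probability; ``fd_mean = 0`` returns a constant trace.
    """
    if n_volumes < 2:
        raise ValueError("FD needs at least 2 consecutive volumes")
    if fd_mean < 0:
        raise ValueError("fd_mean must be non-negative")
    if fd_mean == 0:
        return np.zeros((n_volumes, 6))
    rng = np.random.default_rng(seed)
    mu = fd_mean * n_volumes / (n_volumes - 1)
    if fd_sd > 0:
        shape = (mu / fd_sd) ** 2
        scale = fd_sd**2 / mu
        fd_target = rng.gamma(shape, scale, size=n_volumes - 1)
    else:
        fd_target = np.full(n_volumes - 1, mu)
    weights = rng.dirichlet(np.ones(6), size=n_volumes - 1)
    signs = rng.choice([-1.0, 1.0], size=(n_volumes - 1, 6))
    deltas = fd_target[:, None] * weights * signs
    trace = np.zeros((n_volumes, 6))
    trace[1:] = np.cumsum(deltas, axis=0)
    return trace


def _gamma_normal_corr(shape: float) -> float:
    """Pearson correlation between Z ~ N(0,1) and gamma.ppf(Phi(Z), shape).

    The attenuation factor of the Gaussian-copula quantile transform,
    computed once by quadrature (deterministic).
    """
    from scipy import stats as _sps

    z = np.linspace(-8.0, 8.0, 20001)
    x = _sps.gamma.ppf(_sps.norm.cdf(z), shape)
    phi = _sps.norm.pdf(z)
    ex = np.trapezoid(x * phi, z)
    exz = np.trapezoid(x * z * phi, z)
    ex2 = np.trapezoid(x**2 * phi, z)
    return float(exz / np.sqrt(ex2 - ex**2))


def generate_phenotypes(
    spec: CohortSpec,
    nodal_truth=None,
    mean_fd=None,
    seed_seq=None,
) -> pd.DataFrame:
    """Per-subject phenotype table with a planted symptom-metric association.

    The symptom index keeps a right-skewed gamma marginal (matched to the
    0-28 raw-score range) via a Gaussian copula: a latent normal mixes the
    standardized ``nodal_truth`` with independent noise at a loading chosen
    — after correcting for the Pearson attenuation of the gamma quantile
    transform — so that the partial correlation between index and truth
    given the covariates equals ``spec.effect_size``.  Mild covariate-linked
    shifts are added on the raw scale (and removed again by partialling).
    """
    n = spec.n_subjects
    if spec.effect_size != 0.0:
        if nodal_truth is None:
            raise ValueError("effect_size != 0 requires nodal_truth per subject")
        truth = np.asarray(nodal_truth, dtype=float)
        if truth.shape != (n,):
            raise ValueError("nodal_truth must have one value per subject")
    rng = np.random.default_rng(
        seed_seq if seed_seq is not None else child_seed(spec.seed, _STREAM_PHENOTYPE, 0)
    )
    age = rng.uniform(18.0, 60.0, n)
    sex = rng.choice(["F", "M"], size=n)
    handedness = rng.choice(["right", "left", "ambidextrous"], size=n, p=[0.8, 0.1, 0.1])
    fsiq = rng.normal(100.0, 12.5, n)

    shape = (ADHD_BASE_MEAN / ADHD_BASE_SD) ** 2
    scale = ADHD_BASE_SD**2 / ADHD_BASE_MEAN
    eps = rng.standard_normal(n)
    if spec.effect_size != 0.0:
        z = (truth - truth.mean()) / truth.std()
        loading = spec.effect_size / _gamma_normal_corr(shape)
        if not (-1 < loading < 1):
            raise ValueError(
                f"effect_size {spec.effect_size} too large for the gamma "
                "marginal's copula attenuation"
            )
        latent = loading * z + np.sqrt(1 - loading**2) * eps
    else:
        latent = eps
    from scipy import stats as _sps

    base = _sps.gamma.ppf(_sps.norm.cdf(latent), shape, scale=scale)
    # mild covariate-linked structure (removed again by partialling)
    cov_part = -0.3 * (age - age.mean()) / age.std() + 0.4 * (sex == "M")
    adhd = np.clip(base + cov_part, 0.0, ADHD_MAX)

    adhd_std = (adhd - adhd.mean()) / adhd.std()
    sub = {}
    for name, (m, s) in SUBSCALES.items():
        noise = rng.gamma(2.0, 1.0, n)
        noise = (noise - noise.mean()) / noise.std()
        sub[name] = np.clip(m + s * (0.6 * adhd_std + 0.8 * noise), 0.0, None)

    if mean_fd is None:
        mean_fd = np.clip(rng.normal(spec.fd_mean, spec.fd_sd, n), 0.0, None)
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "adhd_index": adhd,
            **sub,
            "age": age,
            "sex": sex,
            "handedness": handedness,
            "fsiq": fsiq,
            "mean_fd": np.asarray(mean_fd, dtype=float),
        }
    )
    if table.drop(columns=["subject_id"]).isna().any().any():
        raise AssertionError("phenotype table contains missing values")
    return table


def lattice_coordinates(n_nodes: int, spacing: float = 12.0) -> pd.DataFrame:
    """Node coordinates (mm) on a near-cubic 3-D lattice, z-slab raster order.

    Contiguous node-index ranges occupy contiguous z slabs, so planted
    modules (contiguous index blocks) are spatially compact.
    """
    nz = int(np.ceil(n_nodes ** (1 / 3)))
    nx = ny = nz
    while nx * ny * nz < n_nodes:
        nz += 1
    pts = [
        (ix * spacing, iy * spacing, iz * spacing)
        for iz in range(nz)
        for iy in range(ny)
        for ix in range(nx)
    ][:n_nodes]
    arr = np.array(pts)
    return pd.DataFrame(
        {
            "node_id": [f"node-{i:04d}" for i in range(n_nodes)],
            "x": arr[:, 0],
            "y": arr[:, 1],
            "z": arr[:, 2],
        }
    )


def synthetic_network_assignment(n_nodes: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic node-to-network table over the canonical seven networks.

    A stand-in fixture for a real parcellation assignment: nodes are split
    into seven contiguous, roughly equal groups (deterministic given the
    node count; the seed only shuffles nothing here but is kept for
    interface symmetry).
    """
    from .posthoc import NETWORKS_7

    bounds = np.linspace(0, n_nodes, len(NETWORKS_7) + 1).astype(int)
    labels = np.empty(n_nodes, dtype=object)
    for i, nw in enumerate(NETWORKS_7):
        labels[bounds[i]:bounds[i + 1]] = nw
    return pd.DataFrame(
        {"node_id": [f"node-{i:04d}" for i in range(n_nodes)], "network": labels}
    )


def _measured_truth(
    ts: np.ndarray,
    coords: np.ndarray,
    effect_nodes: np.ndarray,
    density: float,
    restarts: int,
    seed: int,
) -> float:
    """Mean measured participation of the effect nodes at one density."""
    r = graphs.correlation_matrix(ts)
    conn = graphs.apply_distance_exclusion(r, coords)
    g = graphs.proportional_threshold(conn, density)
    labels = community.louvain_partition(g, seed=seed, n_restarts=restarts)
    p = cartography.participation_coefficient(g, labels)
    return float(p[effect_nodes].mean())


def generate_cohort(
    spec: CohortSpec,
    truth_density: float = 0.20,
    truth_restarts: int = 3,
) -> Cohort:
    """Full synthetic cohort: time series, motion, phenotypes, coordinates.

    With a nonzero ``effect_size``, each subject's latent trait perturbs the
    effect nodes' between-module correlation, and the "nodal truth" passed
    to the phenotype generator is the *measured* mean participation of the
    effect nodes (single density ``truth_density``, ``truth_restarts``
    Louvain restarts), so the planted partial correlation refers to the
    quantity the pipeline actually estimates.
    """
    coords_df = lattice_coordinates(spec.n_nodes, spec.lattice_spacing)
    coords = coords_df[["x", "y", "z"]].to_numpy()
    eff = np.array(spec.effect_nodes, dtype=int)
    plant = spec.effect_size != 0.0 and eff.size > 0

    latent = None
    if plant:
        rng_lat = np.random.default_rng(child_seed(spec.seed, _STREAM_LATENT, 0))
        latent = np.clip(rng_lat.standard_normal(spec.n_subjects), -2.5, 2.5)

    ts_list, traces, truths = [], [], []
    for s in range(spec.n_subjects):
        boost = float(spec.effect_modulation * latent[s]) if plant else 0.0
        ts = generate_modular_timeseries(
            spec, child_seed(spec.seed, _STREAM_TIMESERIES, s), between_boost=boost
        )
        ts_list.append(ts)
        traces.append(
            generate_motion_trace(
                spec.n_volumes,
                spec.fd_mean,
                spec.fd_sd,
                child_seed(spec.seed, _STREAM_MOTION, s),
            )
        )
        if plant:
            truths.append(
                _measured_truth(
                    ts, coords, eff, truth_density, truth_restarts, seed=spec.seed + s
                )
            )
    truth = np.array(truths) if plant else None
    mean_fds = np.array([motion.mean_fd(t) for t in traces])
    phenotypes = generate_phenotypes(spec, nodal_truth=truth, mean_fd=mean_fds)
    return Cohort(
        spec=spec,
        timeseries=ts_list,
        motion_traces=traces,
        phenotypes=phenotypes,
        coordinates=coords_df,
        nodal_truth=truth,
        latent=latent,
    )


def planted_partition_graph(
    n_nodes: int,
    n_modules: int,
    p_in: float,
    p_out: float,
    seed,
) -> tuple[graphs.BinaryGraph, np.ndarray]:
    """Random binary graph with planted equal modules (stochastic block model).

    Edges appear independently with probability ``p_in`` inside modules and
    ``p_out`` between them.  Returns the graph and the planted labels 1..m.
    """
    if n_nodes % n_modules:
        raise ValueError("n_nodes must divide evenly into n_modules")
    labels = np.repeat(np.arange(1, n_modules + 1), n_nodes // n_modules)
    rng = np.random.default_rng(seed)
    prob = np.where(labels[:, None] == labels[None, :], p_in, p_out)
    upper = np.triu(rng.random((n_nodes, n_nodes)) < prob, 1)
    edges = np.argwhere(upper)
    return graphs.BinaryGraph.from_edges(n_nodes, edges), labels


# ---------------------------------------------------------------------------
# cohort directory I/O

def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write the cohort directory layout consumed by the pipeline.

    ``timeseries/<subject>.tsv`` (header row of node ids),
    ``motion/<subject>.par`` (6 columns, whitespace),
    ``phenotypes.csv``, ``coordinates.csv`` and ``manifest.json`` holding
    the generating spec.
    """
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)
    node_ids = list(cohort.coordinates["node_id"])
    for sid, ts, trace in zip(
        cohort.subject_ids, cohort.timeseries, cohort.motion_traces
    ):
        graphs.write_timeseries_tsv(ts, node_ids, out / "timeseries" / f"{sid}.tsv")
        np.savetxt(out / "motion" / f"{sid}.par", trace, fmt="%.8g")
    cohort.phenotypes.to_csv(out / "phenotypes.csv", index=False, float_format="%.8g")
    cohort.coordinates.to_csv(out / "coordinates.csv", index=False, float_format="%.8g")
    manifest = {"spec": asdict(cohort.spec)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_cohort(cohort_dir) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    spec_dict = dict(manifest["spec"])
    for key in ("module_sizes", "effect_nodes"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = CohortSpec(**spec_dict)
    phenotypes = pd.read_csv(d / "phenotypes.csv")
    coords = pd.read_csv(d / "coordinates.csv")
    ts_list, traces = [], []
    for sid in phenotypes["subject_id"]:
        ts, _ = graphs.read_timeseries_tsv(d / "timeseries" / f"{sid}.tsv")
        ts_list.append(ts)
        traces.append(motion.read_motion_file(d / "motion" / f"{sid}.par"))
    return Cohort(
        spec=spec,
        timeseries=ts_list,
        motion_traces=traces,
        phenotypes=phenotypes,
        coordinates=coords,
        nodal_truth=None,
        latent=None,
    )
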