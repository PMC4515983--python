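"""Synthetic cohorts and marker matrices with the statistical structure the
downstream models assume.

The generator emulates a longitudinal ageing study of three diagnostic groups
(control, preclinical, symptomatic): subjects enter at group-specific ages,
are scanned every couple of years, and non-control subjects carry a clinical
symptom-onset age. Per-vertex log-Jacobian markers follow a continuous
piecewise-linear mean in age — slope ``alpha_prime`` before the subject's
changepoint ``t_symptom - delta_true`` and ``alpha_prime + beta_prime`` after
— on the affected vertex patch of non-control subjects, plus a group offset
``beta``, sex and log-ICV covariate effects, and a two-level Gaussian noise:
a between-subject random effect (variance ``rho * sigma2``) shared by all
scans of a subject and independent within-subject noise (variance
``sigma2``).

Defaults mirror a cohort of 221/50/20 subjects entering at mean ages
55/62/64 with 2.2/2.3/3.6 scans per subject about 2 years apart.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TriMesh, face_areas, log_surface_jacobian

GROUPS = ("control", "preclinical", "symptomatic")


class ParameterError(ValueError):
    pass


@dataclasses.dataclass
class CohortParams:
    """Design-side parameters of the simulated study (ages in years)."""

    n_control: int = 221
    n_preclinical: int = 50
    n_symptomatic: int = 20
    entry_age_mean: tuple[float, float, float] = (55.0, 62.0, 64.0)
    entry_age_sd: tuple[float, float, float] = (8.0, 8.0, 8.0)
    scans_per_subject_mean: tuple[float, float, float] = (2.2, 2.3, 3.6)
    scan_interval_mean: float = 2.02
    onset_offset_mean: float = 6.0
    onset_offset_sd: float = 3.0
    sex_fraction: float = 0.5
    log_icv_mean: float = 14.2
    log_icv_sd: float = 0.12

    def validate(self) -> None:
        if min(self.n_control, self.n_preclinical, self.n_symptomatic) < 0:
            raise ParameterError("group counts must be >= 0")
        if min(self.entry_age_mean) <= 0 or min(self.entry_age_sd) < 0:
            raise ParameterError("entry ages must be positive")
        if self.scan_interval_mean <= 0:
            raise ParameterError("scan interval must be positive")
        if min(self.scans_per_subject_mean) <= 0:
            raise ParameterError("scans per subject must be positive")


@dataclasses.dataclass
class EffectParams:
    """Response-side parameters: fixed effects, changepoint, noise variances.

    Marker units are dimensionless log area ratios; slopes are per year.
    ``rho`` is the ratio of between-subject to within-subject variance.
    """

    n_vertices: int = 100
    affected_vertex_fraction: float = 0.2
    alpha: float = 0.0
    alpha_prime: float = -0.005
    beta: float = -0.05
    beta_prime: float = -0.02
    delta_true: float = 7.0
    gamma: float = 0.01
    delta_icv: float = 0.1
    sigma2: float = 0.01
    rho: float = 0.5
    noise_smooth_halfwidth: int = 0  # optional spatial correlation of the noise

    def validate(self) -> None:
        if self.sigma2 <= 0:
            raise ParameterError("sigma2 must be > 0")
        if self.rho < 0:
            raise ParameterError("rho must be >= 0")
        if self.delta_true < 0:
            raise ParameterError("delta_true must be >= 0")
        if not 0.0 <= self.affected_vertex_fraction <= 1.0:
            raise ParameterError("affected_vertex_fraction must lie in [0, 1]")
        if self.n_vertices < 1:
            raise ParameterError("n_vertices must be >= 1")


@dataclasses.dataclass
class Cohort:
    """Subject table (one row per subject) and scan table (one row per scan).

    subjects: subject_id, group, sex (0/1), log_icv, onset_age (NaN for controls)
    scans:    subject_id, scan_id, scan_age — ages strictly increasing within subject
    """

    subjects: pd.DataFrame
    scans: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_scans(self) -> int:
        return len(self.scans)

    def validate(self) -> None:
        missing = set(self.scans["subject_id"]) - set(self.subjects["subject_id"])
        if missing:
            raise ValueError(f"scan rows reference unknown subjects: {sorted(missing)[:5]}")
        for sid, grp in self.scans.groupby("subject_id"):
            ages = grp["scan_age"].to_numpy()
            if len(ages) > 1 and not np.all(np.diff(ages) > 0):
                raise ValueError(f"scan ages not strictly increasing for subject {sid}")
        subj = self.subjects
        bad = subj[(subj["group"] == "control") & subj["onset_age"].notna()]
        if len(bad):
            raise ValueError("control subjects must not carry an onset age")
        bad = subj[(subj["group"] != "control") & subj["onset_age"].isna()]
        if len(bad):
            raise ValueError("non-control subjects must carry an onset age")

    def first_scans(self) -> "Cohort":
        """Cross-sectional reduction: first scan of every subject."""
        first = self.scans.sort_values(["subject_id", "scan_age"]).groupby(
            "subject_id", as_index=False, sort=False
        ).first()
        first = first.set_index("subject_id").loc[self.subjects["subject_id"]].reset_index()
        return Cohort(self.subjects.copy(), first[["subject_id", "scan_id", "scan_age"]])

    def scan_design(self) -> pd.DataFrame:
        """Scan table joined with subject covariates, in scan-table order."""
        return self.scans.merge(self.subjects, on="subject_id", how="left")


@dataclasses.dataclass
class MarkerMatrix:
    """Per-vertex (rows) by per-scan (columns) log-Jacobian marker values."""

    values: np.ndarray
    scan_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.scan_ids):
            raise ValueError("column count must equal number of scan ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker values must be finite")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


def _truncated_normal(rng, mean, sd, size):
    """Normal draw truncated at +/- 3 SD (re-draw of the tails)."""
    x = rng.normal(mean, sd, size=size)
    while True:
        bad = np.abs(x - mean) > 3 * sd
        if not bad.any() or sd == 0:
            return x
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def generate_cohort(params: CohortParams, seed: int) -> Cohort:
    """Draw a deterministic synthetic cohort.

    Entry ages are truncated normal (+/- 3 SD), scan counts Poisson with a
    minimum of one, scan intervals exponential around the mean interval, and
    the symptom-onset age of non-controls is entry age plus a truncated-normal
    offset — which may exceed the last scan age (symptoms emerging after the
    observation window, as for preclinical subjects).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    counts = (params.n_control, params.n_preclinical, params.n_symptomatic)
    subj_rows = []
    scan_rows = []
    k = 0
    for gi, (group, n) in enumerate(zip(GROUPS, counts)):
        for _ in range(n):
            sid = f"s{k:04d}"
            entry = float(
                _truncated_normal(rng, params.entry_age_mean[gi], params.entry_age_sd[gi], 1)[0]
            )
            n_scans = max(1, int(rng.poisson(params.scans_per_subject_mean[gi])))
            intervals = rng.exponential(params.scan_interval_mean, size=n_scans - 1)
            intervals = np.maximum(intervals, 0.1)  # scanner revisits are months apart at least
            ages = entry + np.concatenate([[0.0], np.cumsum(intervals)])
            if group == "control":
                onset = np.nan
            else:
                onset = entry + float(
                    _truncated_normal(rng, params.onset_offset_mean, params.onset_offset_sd, 1)[0]
                )
            sex = int(rng.random() < params.sex_fraction)
            licv = float(rng.normal(params.log_icv_mean, params.log_icv_sd))
            subj_rows.append((sid, group, sex, licv, onset))
            for j, a in enumerate(ages):
                scan_rows.append((sid, f"{sid}_t{j}", float(a)))
            k += 1
    subjects = pd.DataFrame(
        subj_rows, columns=["subject_id", "group", "sex", "log_icv", "onset_age"]
    )
    scans = pd.DataFrame(scan_rows, columns=["subject_id", "scan_id", "scan_age"])
    cohort = Cohort(subjects, scans)
    cohort.validate()
    return cohort


def affected_patch(effects: EffectParams, mesh: TriMesh | None = None, seed_vertex: int = 0) -> np.ndarray:
    """Boolean mask of affected vertices: a contiguous patch grown breadth-first
    from ``seed_vertex`` over the mesh edges when a mesh is supplied, else a
    contiguous index block (the vertex ordering standing in for adjacency)."""
    n_aff = int(round(effects.affected_vertex_fraction * effects.n_vertices))
    mask = np.zeros(effects.n_vertices, dtype=bool)
    if n_aff == 0:
        return mask
    if mesh is None:
        mask[:n_aff] = True
        return mask
    adj: dict[int, set[int]] = {i: set() for i in range(mesh.n_vertices)}
    for a, b, c in mesh.faces:
        adj[a].update((b, c)); adj[b].update((a, c)); adj[c].update((a, b))
    frontier = [seed_vertex]
    chosen: list[int] = []
    seen = {seed_vertex}
    while frontier and len(chosen) < n_aff:
        nxt: list[int] = []
        for v in frontier:
            if len(chosen) >= n_aff:
                break
            chosen.append(v)
            for w in sorted(adj[v]):
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        frontier = nxt
    mask[np.array(chosen[:n_aff])] = True
    return mask


def _smooth_noise(noise: np.ndarray, halfwidth: int) -> np.ndarray:
    """Moving-average smoothing over the vertex axis, rescaled to preserve the
    marginal variance (vertex correlation only; models treat vertices marginally)."""
    if halfwidth <= 0:
        return noise
    w = 2 * halfwidth + 1
    kernel = np.ones(w) / w
    padded = np.pad(noise, ((halfwidth, halfwidth), (0, 0)), mode="wrap")
    out = np.empty_like(noise)
    for j in range(noise.shape[1]):
        out[:, j] = np.convolve(padded[:, j], kernel, mode="valid")
    return out * np.sqrt(w)


def marker_mean(cohort: Cohort, effects: EffectParams, mesh: TriMesh | None = None) -> np.ndarray:
    """Noise-free mean marker surface (n_vertices, n_scans) under the
    continuous changepoint mean model."""
    design = cohort.scan_design()
    a = design["scan_age"].to_numpy()
    g = (design["group"] != "control").to_numpy().astype(float)
    d = design["sex"].to_numpy().astype(float)
    i_c = design["log_icv"].to_numpy() - design["log_icv"].mean()
    onset = design["onset_age"].to_numpy()
    cp = onset - effects.delta_true
    past = np.where(np.isnan(cp), 0.0, np.clip(a - cp, 0.0, None))  # (a - cp) H(a - cp)
    base = effects.alpha + effects.alpha_prime * a + effects.gamma * d + effects.delta_icv * i_c
    bump = g * (effects.beta + effects.beta_prime * past)
    mask = affected_patch(effects, mesh)
    mean = np.tile(base, (effects.n_vertices, 1))
    mean[mask] += bump
    return mean


def generate_markers(
    cohort: Cohort, effects: EffectParams, seed: int, mesh: TriMesh | None = None
) -> MarkerMatrix:
    """Draw a marker matrix: changepoint mean + between-subject random effect
    (variance rho*sigma2) + within-subject noise (variance sigma2)."""
    effects.validate()
    if cohort.n_scans == 0:
        raise ParameterError("cohort has no scans")
    rng = np.random.default_rng(seed)
    design = cohort.scan_design()
    mean = marker_mean(cohort, effects, mesh)
    sigma = np.sqrt(effects.sigma2)
    n_v = effects.n_vertices
    subj_ids = cohort.subjects["subject_id"].to_numpy()
    subj_pos = {s: i for i, s in enumerate(subj_ids)}
    col_subj = np.array([subj_pos[s] for s in design["subject_id"]])
    eta = _smooth_noise(
        rng.normal(0.0, sigma * np.sqrt(effects.rho), size=(n_v, len(subj_ids))),
        effects.noise_smooth_halfwidth,
    )
    zeta = _smooth_noise(
        rng.normal(0.0, sigma, size=(n_v, cohort.n_scans)), effects.noise_smooth_halfwidth
    )
    values = mean + eta[:, col_subj] + zeta
    return MarkerMatrix(values, design["scan_id"].tolist())


def _smooth_indicator(mesh: TriMesh, w: np.ndarray, rounds: int = 2) -> np.ndarray:
    """Average a vertex field over {vertex + neighbors} a few times."""
    adj: dict[int, set[int]] = {i: {i} for i in range(mesh.n_vertices)}
    for a, b, c in mesh.faces:
        adj[a].update((b, c)); adj[b].update((a, c)); adj[c].update((a, b))
    nb = [np.fromiter(adj[i], dtype=np.int64) for i in range(mesh.n_vertices)]
    for _ in range(rounds):
        w = np.array([w[nb[i]].mean() for i in range(mesh.n_vertices)])
    return w


def generate_deformed_meshes(
    template: TriMesh, effects: EffectParams, cohort: Cohort, seed: int
) -> tuple[list[TriMesh], np.ndarray]:
    """Per-scan deformed copies of the template realizing the marker model
    geometrically: a smooth radial contraction of the affected patch toward its
    centroid, scaled so the mean log area change tracks each scan's model mean.

    Returns the meshes and the true log-Jacobian field (n_vertices, n_scans),
    recorded by direct area recomputation against the template.
    """
    if template.n_vertices != effects.n_vertices:
        raise ParameterError("template vertex count must equal effects.n_vertices")
    mean = marker_mean(cohort, effects, template)
    mask = affected_patch(effects, template)
    centroid = template.vertices[mask].mean(0) if mask.any() else template.vertices.mean(0)
    # smooth falloff at the patch boundary: the affected-vertex indicator
    # averaged twice over mesh neighborhoods (stays exactly 1 when the whole
    # surface is affected, so a uniform target gives a uniform scaling)
    weight = _smooth_indicator(template, mask.astype(float), rounds=2)
    meshes: list[TriMesh] = []
    true_j = np.empty((template.n_vertices, mean.shape[1]))
    for j in range(mean.shape[1]):
        target = mean[:, j]  # target log area change per vertex
        # radial scaling toward the centroid scales local areas ~ factor^2
        factor = 1.0 + weight * (np.exp(0.5 * target) - 1.0)
        verts = centroid + (template.vertices - centroid) * factor[:, None]
        deformed = template.with_vertices(verts)
        if np.any(face_areas(deformed) <= 0):
            raise ParameterError(f"contraction produced degenerate triangles at scan {j}")
        meshes.append(deformed)
        true_j[:, j] = log_surface_jacobian(template, deformed)
    return meshes, true_j


# ---------------------------------------------------------------------------
# I/O: CSV cohort, TSV markers, JSON sidecar
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: Cohort, path: str | Path, seed: int | None = None,
                     params: CohortParams | None = None) -> None:
    df = cohort.scan_design()[
        ["subject_id", "group", "sex", "log_icv", "onset_age", "scan_id", "scan_age"]
    ]
    df.to_csv(path, index=False)
    _write_sidecar(path, seed, params)


def read_cohort_csv(path: str | Path) -> Cohort:
    df = pd.read_csv(path)
    subjects = df.drop_duplicates("subject_id")[
        ["subject_id", "group", "sex", "log_icv", "onset_age"]
    ].reset_index(drop=True)
    scans = df[["subject_id", "scan_id", "scan_age"]].reset_index(drop=True)
    cohort = Cohort(subjects, scans)
    cohort.validate()
    return cohort


def write_markers_tsv(markers: MarkerMatrix, path: str | Path, seed: int | None = None,
                      params: EffectParams | None = None) -> None:
    pd.DataFrame(markers.values, columns=markers.scan_ids).to_csv(path, sep="\t", index=False)
    _write_sidecar(path, seed, params)


def read_markers_tsv(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t")
    return MarkerMatrix(df.to_numpy(), [str(c) for c in df.columns])


def _write_sidecar(path: str | Path, seed, params) -> None:
    meta: dict = {}
    if seed is not None:
        meta["seed"] = int(seed)
    if params is not None:
        meta["params"] = dataclasses.asdict(params)
    if meta:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, default=str))


# ---------------------------------------------------------------------------
# Test geometry
# ---------------------------------------------------------------------------

def icosphere(subdivisions: int = 2, radius: float = 10.0) -> TriMesh:
    """Subdivided icosahedron (42 vertices at 1 subdivision, 162 at 2, ...)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    vlist = [tuple(v) for v in verts]
    cache: dict[tuple[int, int], int] = {}

    def midpoint(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in cache:
            m = np.asarray(vlist[a]) + np.asarray(vlist[b])
            m /= np.linalg.norm(m)
            vlist.append(tuple(m))
            cache[key] = len(vlist) - 1
        return cache[key]

    for _ in range(subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return TriMesh(np.asarray(vlist) * radius, np.asarray(faces))
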