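"""Synthetic cortical cohort with the statistical structure the pipeline assumes.

The real study data (HCP Young Adult, restricted access) cannot be shipped;
this module generates a stand-in cohort with the same shape and the key
planted effects:

* closed hemisphere meshes (icosphere, order 3 → 642 vertices, 50 mm radius)
  with smooth radial "folding" bumps shared across the cohort;
* a K=35 Voronoi parcellation from a cohort-level atlas of seed vertices,
  jittered per subject to mimic inter-subject anatomical variability;
* cortical thickness with region-specific baselines, a planted negative
  linear age effect, a per-subject random intercept, and vertex-wise noise —
  calibrated so the cohort-level mean-thickness vs. age correlation has
  population value ≈ −0.35;
* signed curvature, negative on gyral crowns (outward bumps) and positive
  in sulcal pits (inward bumps);
* nonnegative block-structured connectivity rows of fixed length 642
  (the low-resolution template grid), with within-region strength above
  between-region strength;
* demographics: age uniform on 22–35 years, near-ceiling MMSE (28–30), and
  discrete education levels; hemisphere records of one individual share
  demographics.

Determinism: a master seed feeds a ``numpy.random.SeedSequence``; the cohort
stream is child 0 and subject *i* uses child *i+1*, so cohorts are
bit-reproducible and individual subjects are independent.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse import csgraph

from .surface_mesh import SurfaceMesh, build_icosphere, mesh_to_graph

logger = logging.getLogger(__name__)

__all__ = [
    "CohortParams",
    "ConnectivityMap",
    "Subject",
    "Cohort",
    "voronoi_parcellate",
    "synth_morphometry",
    "synth_connectivity",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

N_TEMPLATE_COLUMNS = 642  # fsaverage3-resolution connectivity grid


@dataclass
class ConnectivityMap:
    """Vertex-to-template conductance matrix, V rows × 642 columns, ≥ 0."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_TEMPLATE_COLUMNS:
            raise ValueError(
                f"connectivity must have {N_TEMPLATE_COLUMNS} columns, "
                f"got shape {self.matrix.shape}"
            )
        if (self.matrix < 0).any():
            raise ValueError("conductance values must be nonnegative")

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]


@dataclass
class CohortParams:
    """Generator configuration; the defaults are the emulated study conditions."""

    n_subjects: int = 97
    k_regions: int = 35
    subdivisions: int = 3
    radius: float = 50.0                       # mm
    hemispheres: tuple[str, ...] = ("L", "R")
    include_connectivity: bool = True

    age_range: tuple[float, float] = (22.0, 35.0)   # years (healthy young adults)
    beta_age: float = -0.01                    # mm thinning per year, planted effect
    subject_sd: float = 0.0992                 # mm, subject random intercept; combined
                                               # with vertex noise and atlas jitter this
                                               # puts the population mean-thickness/age
                                               # correlation at r = -0.35
    thickness_noise_sd: float = 0.3            # mm, vertex-wise noise
    base_range: tuple[float, float] = (1.5, 4.5)    # mm, region baseline thickness

    n_bumps: int = 24                          # folding bumps per hemisphere
    bump_kappa: float = 30.0                   # bump concentration on the sphere
    displacement_frac: float = 0.08            # radial displacement amplitude
    curvature_scale: float = 0.3               # 1/mm, curvature magnitude scale

    conn_within: float = 1.0                   # within-region conductance
    conn_between: float = 0.2                  # mean between-region conductance
    conn_between_jitter: float = 0.1           # half-width of between-region variation
    conn_noise_sd: float = 0.05                # vertex-level conductance noise

    atlas_jitter_prob: float = 0.5             # per-seed chance of a one-hop move

    mmse_values: tuple[int, ...] = (28, 29, 30)
    mmse_probs: tuple[float, ...] = (0.2, 0.35, 0.45)
    education_values: tuple[int, ...] = (12, 13, 14, 16, 17, 18, 20)
    education_probs: tuple[float, ...] = (0.1, 0.1, 0.2, 0.25, 0.15, 0.1, 0.1)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.k_regions < 1:
            raise ValueError("k_regions must be >= 1")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be increasing")


@dataclass
class Subject:
    """One hemisphere of one individual."""

    id: str
    hemisphere: str
    mesh: SurfaceMesh
    labels: np.ndarray
    thickness: np.ndarray
    curvature: np.ndarray
    connectivity: ConnectivityMap | None
    age: float
    mmse: int
    education: int

    def __post_init__(self) -> None:
        v = self.mesh.n_vertices
        for name in ("labels", "thickness", "curvature"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != v:
                raise ValueError(f"{name} has length {len(arr)}, expected {v}")
            setattr(self, name, arr)
        self.labels = self.labels.astype(np.int64)
        if (self.thickness <= 0).any():
            raise ValueError("thickness must be positive")
        if self.connectivity is not None and self.connectivity.n_vertices != v:
            raise ValueError("connectivity row count must equal vertex count")


@dataclass
class Cohort:
    """Generated subjects plus the cohort-level structures they share."""

    subjects: list[Subject]
    base_mesh: SurfaceMesh
    atlas_labels: np.ndarray          # reference parcellation on the base mesh
    lowres_labels: np.ndarray         # parcellation of the 642-column template grid
    region_bases: np.ndarray          # per-region baseline thickness (mm)
    template: np.ndarray              # K×K region-level conductance template
    params: CohortParams

    def filter(self, hemisphere: str) -> list[Subject]:
        return [s for s in self.subjects if s.hemisphere == hemisphere]

    @property
    def individual_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s.id)
        return list(seen)


def voronoi_parcellate(
    mesh: SurfaceMesh,
    k: int,
    seed: int | np.random.Generator | None = None,
    seed_vertices: np.ndarray | None = None,
) -> np.ndarray:
    """Graph-Voronoi parcellation into ``k`` connected regions.

    ``k`` seed vertices are sampled without replacement (or given
    explicitly); every vertex takes the label of the seed with minimal hop
    distance, ties broken toward the lower seed index.  With that
    tie-breaking every region is nonempty and connected in the vertex graph.
    """
    v = mesh.n_vertices
    if k > v:
        raise ValueError(f"K={k} exceeds vertex count {v}")
    if seed_vertices is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        seed_vertices = rng.choice(v, size=k, replace=False)
    else:
        seed_vertices = np.asarray(seed_vertices, dtype=np.int64)
        if len(seed_vertices) != k or len(np.unique(seed_vertices)) != k:
            raise ValueError("seed_vertices must be k distinct vertex indices")
    adj = mesh_to_graph(mesh).adjacency()
    dist = csgraph.dijkstra(adj, unweighted=True, indices=seed_vertices)
    return np.argmin(dist, axis=0).astype(np.int64)  # first minimum -> lowest seed index


def _bump_field(unit_dirs: np.ndarray, centers: np.ndarray, amps: np.ndarray,
                kappa: float) -> np.ndarray:
    """Smooth field on the sphere: sum of von-Mises–Fisher-shaped bumps."""
    cosines = unit_dirs @ centers.T              # (V, n_bumps)
    return np.exp(kappa * (cosines - 1.0)) @ amps


def synth_morphometry(
    mesh: SurfaceMesh,
    labels: np.ndarray,
    age: float,
    params: CohortParams,
    seed: int | np.random.Generator,
    region_bases: np.ndarray | None = None,
    bump_centers: np.ndarray | None = None,
    bump_amps: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-vertex thickness and curvature, plus the displaced mesh vertices.

    thickness(v) = base(label(v)) + β·(age − age_mean) + subject offset
                   + N(0, σ_vertex), floored at 0.1 mm.

    Curvature derives from a radial bump field g: vertices displaced outward
    (gyral crowns, g > 0) get negative curvature, inward (sulcal pits,
    g < 0) positive; magnitude scaled to ``curvature_scale`` (1/mm).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = mesh.n_vertices
    labels = np.asarray(labels)
    k = int(labels.max()) + 1

    if region_bases is None:
        region_bases = rng.uniform(*params.base_range, size=k)
    if bump_centers is None:
        raw = rng.normal(size=(params.n_bumps, 3))
        bump_centers = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    if bump_amps is None:
        signs = np.where(np.arange(params.n_bumps) % 2 == 0, 1.0, -1.0)
        bump_amps = signs * rng.uniform(0.5, 1.0, size=params.n_bumps)

    age_mean = 0.5 * (params.age_range[0] + params.age_range[1])
    thickness = (
        region_bases[labels]
        + params.beta_age * (age - age_mean)
        + rng.normal(0.0, params.subject_sd)
        + rng.normal(0.0, params.thickness_noise_sd, size=v)
    )
    n_clipped = int((thickness < 0.1).sum())
    if n_clipped:
        logger.warning("clipped %d nonpositive thickness values to 0.1 mm", n_clipped)
        thickness = np.maximum(thickness, 0.1)

    radii = np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    unit = mesh.vertices / radii
    g = _bump_field(unit, bump_centers, bump_amps, params.bump_kappa)
    gmax = np.abs(g).max() or 1.0
    g_norm = g / gmax
    curvature = -params.curvature_scale * g_norm
    displaced = unit * radii * (1.0 + params.displacement_frac * g_norm[:, None])
    return thickness, curvature, displaced


def synth_connectivity(
    labels: np.ndarray,
    lowres_labels: np.ndarray,
    params: CohortParams,
    seed: int | np.random.Generator,
    template: np.ndarray | None = None,
) -> ConnectivityMap:
    """Block-structured conductance rows over the 642-column template grid.

    Entry (v, j) = template(label(v), lowres_label(j)) + truncated noise,
    where the K×K template is symmetric, nonnegative, and has within-region
    strength strictly above every between-region strength.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=np.int64)
    lowres_labels = np.asarray(lowres_labels, dtype=np.int64)
    if len(lowres_labels) != N_TEMPLATE_COLUMNS:
        raise ValueError(
            f"lowres labeling must cover the {N_TEMPLATE_COLUMNS}-vertex grid"
        )
    k = max(labels.max(), lowres_labels.max()) + 1
    if template is None:
        template = region_template(int(k), params, rng)
    block = template[np.ix_(labels, lowres_labels)]
    noisy = block + rng.normal(0.0, params.conn_noise_sd, size=block.shape)
    return ConnectivityMap(np.maximum(noisy, 0.0))


def region_template(k: int, params: CohortParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Symmetric nonnegative K×K region conductance template."""
    off = rng.uniform(
        max(params.conn_between - params.conn_between_jitter, 0.0),
        params.conn_between + params.conn_between_jitter,
        size=(k, k),
    )
    template = (off + off.T) / 2.0
    np.fill_diagonal(template, params.conn_within)
    return template


def _jitter_seeds(atlas_seeds: np.ndarray, adjacency, prob: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Move each atlas seed to a random neighbor with probability ``prob``,
    resampling on collisions so seeds stay distinct."""
    seeds = atlas_seeds.copy()
    indptr, indices = adjacency.indptr, adjacency.indices
    for i in range(len(seeds)):
        if rng.random() >= prob:
            continue
        neigh = indices[indptr[seeds[i]]:indptr[seeds[i] + 1]]
        candidates = rng.permutation(neigh)
        for c in candidates:
            if c not in seeds:
                seeds[i] = c
                break
    return seeds


def generate_cohort(params: CohortParams) -> Cohort:
    """Generate the full cohort deterministically from the master seed."""
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_subjects + 1)
    cohort_rng = np.random.default_rng(children[0])

    base_mesh = build_icosphere(params.subdivisions, radius=params.radius)
    v = base_mesh.n_vertices
    graph = mesh_to_graph(base_mesh)
    adjacency = graph.adjacency()

    atlas_seeds = cohort_rng.choice(v, size=params.k_regions, replace=False)
    atlas_labels = voronoi_parcellate(base_mesh, params.k_regions,
                                      seed_vertices=atlas_seeds)

    if v == N_TEMPLATE_COLUMNS:
        lowres_labels = atlas_labels
    else:
        lowres_mesh = build_icosphere(3, radius=params.radius)
        lowres_labels = voronoi_parcellate(lowres_mesh, params.k_regions,
                                           seed=cohort_rng)

    region_bases = cohort_rng.uniform(*params.base_range, size=params.k_regions)
    template = region_template(params.k_regions, params, cohort_rng)

    raw = cohort_rng.normal(size=(params.n_bumps, 3))
    bump_centers = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    signs = np.where(np.arange(params.n_bumps) % 2 == 0, 1.0, -1.0)
    bump_amps = signs * cohort_rng.uniform(0.5, 1.0, size=params.n_bumps)

    subjects: list[Subject] = []
    for i in range(params.n_subjects):
        subj_rng = np.random.default_rng(children[i + 1])
        age = float(subj_rng.uniform(*params.age_range))
        mmse = int(subj_rng.choice(params.mmse_values, p=params.mmse_probs))
        education = int(subj_rng.choice(params.education_values,
                                        p=params.education_probs))
        sid = f"sub-{i:03d}"
        for hemi in params.hemispheres:
            seeds = _jitter_seeds(atlas_seeds, adjacency,
                                  params.atlas_jitter_prob, subj_rng)
            labels = voronoi_parcellate(base_mesh, params.k_regions,
                                        seed_vertices=seeds)
            thickness, curvature, displaced = synth_morphometry(
                base_mesh, labels, age, params, subj_rng,
                region_bases=region_bases,
                bump_centers=bump_centers, bump_amps=bump_amps,
            )
            verts = displaced.copy()
            if hemi == "R":
                verts[:, 0] *= -1.0  # mirror across the midsagittal plane
            connectivity = None
            if params.include_connectivity:
                connectivity = synth_connectivity(
                    labels, lowres_labels, params, subj_rng, template=template
                )
            subjects.append(Subject(
                id=sid, hemisphere=hemi,
                mesh=SurfaceMesh(vertices=verts, faces=base_mesh.faces),
                labels=labels, thickness=thickness, curvature=curvature,
                connectivity=connectivity,
                age=age, mmse=mmse, education=education,
            ))
    return Cohort(
        subjects=subjects, base_mesh=base_mesh, atlas_labels=atlas_labels,
        lowres_labels=lowres_labels, region_bases=region_bases,
        template=template, params=params,
    )


def save_cohort(cohort: Cohort, directory: str | os.PathLike) -> None:
    """Write a cohort directory: CSV manifest + per-subject files.

    Meshes are FreeSurfer binary surfaces, thickness/curvature FreeSurfer
    curv overlays, labels annot files, connectivity row-major ``.npy``
    matrices (shape header included in the format).
    """
    import pandas as pd

    from . import surface_io

    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        stem = f"{s.id}_{s.hemisphere}"
        surface_io.write_surface(os.path.join(directory, stem + ".surf"), s.mesh)
        surface_io.write_overlay(os.path.join(directory, stem + ".thickness"), s.thickness)
        surface_io.write_overlay(os.path.join(directory, stem + ".curv"), s.curvature)
        surface_io.write_labels(os.path.join(directory, stem + ".annot"), s.labels)
        conn_path = ""
        if s.connectivity is not None:
            conn_path = stem + "_conn.npy"
            np.save(os.path.join(directory, conn_path), s.connectivity.matrix)
        rows.append({
            "subject_id": s.id, "hemisphere": s.hemisphere, "age": s.age,
            "mmse": s.mmse, "education": s.education,
            "surface": stem + ".surf", "thickness": stem + ".thickness",
            "curvature": stem + ".curv", "labels": stem + ".annot",
            "connectivity": conn_path,
        })
    pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.csv"), index=False)
    meta = asdict(cohort.params)
    with open(os.path.join(directory, "cohort.json"), "w") as fh:
        json.dump({
            "params": meta,
            "atlas_labels": cohort.atlas_labels.tolist(),
            "lowres_labels": cohort.lowres_labels.tolist(),
            "region_bases": cohort.region_bases.tolist(),
            "template": cohort.template.tolist(),
        }, fh)


def load_cohort(directory: str | os.PathLike) -> Cohort:
    import pandas as pd

    from . import surface_io

    directory = str(directory)
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"),
                           keep_default_na=False)
    with open(os.path.join(directory, "cohort.json")) as fh:
        meta = json.load(fh)
    params = CohortParams(**{**meta["params"],
                             "hemispheres": tuple(meta["params"]["hemispheres"]),
                             "age_range": tuple(meta["params"]["age_range"]),
                             "base_range": tuple(meta["params"]["base_range"]),
                             "mmse_values": tuple(meta["params"]["mmse_values"]),
                             "mmse_probs": tuple(meta["params"]["mmse_probs"]),
                             "education_values": tuple(meta["params"]["education_values"]),
                             "education_probs": tuple(meta["params"]["education_probs"])})
    subjects = []
    for _, row in manifest.iterrows():
        mesh = surface_io.read_surface(os.path.join(directory, row["surface"]))
        conn = None
        if row["connectivity"]:
            conn = ConnectivityMap(np.load(os.path.join(directory, row["connectivity"])))
        subjects.append(Subject(
            id=row["subject_id"], hemisphere=row["hemisphere"], mesh=mesh,
            labels=surface_io.read_labels(os.path.join(directory, row["labels"]),
                                          expected_vertices=mesh.n_vertices),
            thickness=surface_io.read_overlay(os.path.join(directory, row["thickness"]),
                                              expected_vertices=mesh.n_vertices),
            curvature=surface_io.read_overlay(os.path.join(directory, row["curvature"]),
                                              expected_vertices=mesh.n_vertices),
            connectivity=conn,
            age=float(row["age"]), mmse=int(row["mmse"]), education=int(row["education"]),
        ))
    base_mesh = build_icosphere(params.subdivisions, radius=params.radius)
    return Cohort(
        subjects=subjects, base_mesh=base_mesh,
        atlas_labels=np.asarray(meta["atlas_labels"], dtype=np.int64),
        lowres_labels=np.asarray(meta["lowres_labels"], dtype=np.int64),
        region_bases=np.asarray(meta["region_bases"]),
        template=np.asarray(meta["template"]),
        params=params,
    )
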