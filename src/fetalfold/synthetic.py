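"""Synthetic folded-surface cohorts with known ground truth.

The generator emulates the statistical structure of a fetal cohort: closed
genus-0 hemispheric surfaces whose size and folding increase with
gestational age (GA), a cohort with the study's GA distribution and sex
ratio, and a brain-age gap (PAD) generated from a linear model in GA and
chosen measures with known effect sizes.  Surfaces are icospheres displaced
radially by a band-limited spherical-harmonic field (the folding) plus
optional discrete Gaussian pits (exact-depth phantoms).  Because the
displacement is purely radial, the surface is embedded whenever the radius
stays positive, which the generator enforces.

Everything is a pure function of (spec, model, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import trimesh as _trimesh
from scipy.sparse.csgraph import dijkstra
from scipy.special import sph_harm_y
from scipy.stats import truncnorm

from .mesh import TriMesh

__all__ = [
    "GrowthModel",
    "CohortSpec",
    "Pit",
    "synth_surface",
    "synth_parcellation",
    "synth_cohort",
    "synth_cohort_table",
    "synth_template",
    "fibonacci_directions",
]


@dataclasses.dataclass
class Pit:
    """A discrete radial pit: inward Gaussian dent of known depth."""

    direction: np.ndarray  # unit vector
    depth: float  # mm
    sigma: float = 1.0  # mm, tangential width
    power: int = 2  # radial profile exp(-(s/sigma)^power / 2); use 4 for a
    # steep-walled well that the 7.5 mm closing ball cannot descend into


@dataclasses.dataclass
class GrowthModel:
    """Couplings of size and folding to gestational age.

    radius r(GA) = r0 + r1*GA (mm); fold RMS amplitude
    a(GA) = max(0, a1*(GA - ga_onset)) (mm).  Folding lives in the
    spherical-harmonic degrees whose angular wavelength 2*pi*r/l falls in
    ``wavelengths`` (mm): sulcal spacing in real fetal cortex is roughly
    size-invariant in millimetres (new folds appear as the brain grows
    rather than existing folds stretching), so the degree band moves up
    with radius.  Defaults give ~16 mm hemispheric radius at 20 GW growing
    to ~29 mm at 38 GW, with folding onset near 22 GW — the monotone
    size/folding couplings a fetal cohort shows.
    """

    r0: float = 2.0
    r1: float = 0.7  # mm per week
    a1: float = 0.25  # mm fold amplitude per week past onset
    ga_onset: float = 22.0
    fold_wavelength: float = 14.0  # mm, centre of the fold spectrum
    fold_bandwidth: float = 0.25  # log-wavelength SD of the spectral envelope
    degrees: tuple[int, ...] = tuple(range(4, 31))
    subdivisions: int = 4

    def radius(self, ga: float) -> float:
        r = self.r0 + self.r1 * ga
        if r <= 0:
            raise ValueError(f"non-positive radius at GA={ga}")
        return r

    def amplitude(self, ga: float) -> float:
        return max(0.0, self.a1 * (ga - self.ga_onset))

    def spectral_weights(self, radius: float) -> np.ndarray:
        """Per-coefficient envelope weight: a log-normal bump over the
        degree's wavelength 2*pi*r/l centred on ``fold_wavelength``.

        The envelope varies continuously with radius, so the folding
        spectrum *in millimetres* — and with it the gyrification index —
        is smooth in, and essentially independent of, brain size.
        """
        w = []
        for l in self.degrees:
            lam = 2 * np.pi * radius / l
            wl = np.exp(
                -np.log(lam / self.fold_wavelength) ** 2
                / (2 * self.fold_bandwidth**2)
            )
            w.extend([wl] * (2 * l + 1))
        return np.asarray(w)

    def n_coeffs(self) -> int:
        return sum(2 * l + 1 for l in self.degrees)


@dataclasses.dataclass
class CohortSpec:
    """Cohort composition and the PAD generating model.

    PAD_i = sum_m gamma[m] * z(X_m,i) + gamma_int * z(X)_i * male_i + eps,
    eps ~ N(0, sigma_pad).  ``radius_jitter``/``amp_jitter`` add per-subject
    geometric variability independent of GA so measures carry information
    beyond the age trend.
    """

    n: int = 115
    ga_mean: float = 29.4
    ga_sd: float = 4.4
    ga_range: tuple[float, float] = (19.9, 38.7)
    sex_ratio: tuple[int, int, int] = (57, 42, 16)  # M : F : unknown
    gamma: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"cerebral_volume": 0.6, "surface_area": 0.6}
    )
    gamma_int: float = 0.0
    interaction_measure: str | None = None
    sigma_pad: float = 0.6  # weeks
    radius_jitter: float = 1.5  # mm; size varies notably between subjects
    amp_jitter: float = 0.0  # mm; sulcation stage is treated as fully
    # age-determined in the default cohort (pattern randomness remains):
    # amplitude jitter mechanically couples surface area to GI, which would
    # put folding-borne signal into PAD; raise for sensitivity analyses
    seed: int = 0


def fibonacci_directions(k: int) -> np.ndarray:
    """k well-spread unit directions (Fibonacci sphere), deterministic."""
    i = np.arange(k) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / k
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


_BASIS_CACHE: dict[tuple, np.ndarray] = {}


def _real_harmonic_basis(degrees: tuple[int, ...], dirs: np.ndarray) -> np.ndarray:
    """Real spherical-harmonic basis at unit directions, (n, C), cached per
    (degree band, vertex count) since icosphere directions are shared."""
    key = (degrees, len(dirs))
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))  # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])  # azimuth
    cols = []
    for l in degrees:
        for m in range(-l, l + 1):
            Y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2) * Y.imag)
            elif m == 0:
                cols.append(Y.real)
            else:
                cols.append(np.sqrt(2) * Y.real)
    B = np.stack(cols, axis=1)
    _BASIS_CACHE[key] = B
    return B


def sample_fold_coeffs(model: GrowthModel, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal coefficients for the folding field, one per (l, m)."""
    return rng.standard_normal(model.n_coeffs())


def synth_surface(
    ga: float,
    model: GrowthModel | None = None,
    seed: int = 0,
    coeffs: np.ndarray | None = None,
    pits: tuple[Pit, ...] = (),
    radius: float | None = None,
    amplitude: float | None = None,
) -> tuple[TriMesh, dict]:
    """Folded sphere at gestational age ``ga``; returns (mesh, truth).

    ``truth`` records radius, amplitude, coefficients, and for each pit the
    index of the vertex at its bottom.  Raises when the folding would drive
    the radius non-positive (a radial graph is embedded iff r > 0).
    """
    model = model or GrowthModel()
    rng = np.random.default_rng(seed)
    base = _trimesh.creation.icosphere(subdivisions=model.subdivisions, radius=1.0)
    dirs = np.asarray(base.vertices)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)

    r_ga = model.radius(ga) if radius is None else float(radius)
    a_ga = model.amplitude(ga) if amplitude is None else float(amplitude)
    R = np.full(len(dirs), r_ga)
    if a_ga > 0:
        if coeffs is None:
            coeffs = sample_fold_coeffs(model, rng)
        B = _real_harmonic_basis(model.degrees, dirs)
        if len(coeffs) != B.shape[1]:
            raise ValueError(
                f"{len(coeffs)} coefficients, {B.shape[1]} expected for "
                f"degrees {model.degrees[0]}..{model.degrees[-1]}"
            )
        field = B @ (model.spectral_weights(r_ga) * coeffs)
        field = field - field.mean()
        rms = np.sqrt(np.mean(field**2))
        if rms > 0:
            R = R + a_ga * field / rms

    pit_vertices = []
    for pit in pits:
        d = np.asarray(pit.direction, dtype=float)
        d = d / np.linalg.norm(d)
        ang = np.arccos(np.clip(dirs @ d, -1, 1))
        arc = r_ga * ang  # tangential distance along the sphere, mm
        R = R - pit.depth * np.exp(-((arc / pit.sigma) ** pit.power) / 2)
        pit_vertices.append(int(np.argmax(dirs @ d)))

    if R.min() <= max(0.5, 0.05 * r_ga):
        raise ValueError(
            f"folding amplitude {a_ga:.2f} mm collapses the radius "
            f"(min {R.min():.2f} mm) — surface would self-intersect"
        )
    mesh = TriMesh(dirs * R[:, None], np.asarray(base.faces), closed=True)
    truth = {
        "ga": ga,
        "radius": r_ga,
        "amplitude": a_ga,
        "coeffs": coeffs,
        "pit_vertices": pit_vertices,
    }
    return mesh, truth


def _edge_graph(mesh: TriMesh) -> sp.csr_matrix:
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.coo_matrix(
        (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(n, n)
    )
    return g.tocsr()


def synth_parcellation(mesh: TriMesh, n_regions: int = 21, seed: int = 0) -> np.ndarray:
    """Geodesic-Voronoi parcellation into contiguous regions, labels 1..n.

    Seeds are farthest-point samples on the edge-length graph, so regions
    are compact and every vertex is labeled.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > mesh.n_vertices:
        raise ValueError("more regions than vertices")
    g = _edge_graph(mesh)
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(mesh.n_vertices))]
    d = dijkstra(g, indices=seeds[0])
    for _ in range(n_regions - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, dijkstra(g, indices=nxt))
    dists = dijkstra(g, indices=seeds)  # (k, n)
    return np.argmin(dists, axis=0) + 1


def _draw_sexes(n: int, ratio: tuple[int, int, int], rng: np.random.Generator):
    p = np.asarray(ratio, dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(["M", "F", "unknown"]), size=n, p=p)


def synth_cohort_table(
    n: int = 115,
    gamma: dict[str, float] | None = None,
    gamma_int: float = 0.0,
    interaction_measure: str | None = None,
    sigma_pad: float = 1.0,
    measures: tuple[str, ...] = ("cerebral_volume", "surface_area", "gyrification_index"),
    ga_coupling: float = 0.7,
    spec: CohortSpec | None = None,
    seed: int = 0,
):
    """Table-level cohort (no meshes) for statistical calibration.

    Each measure column is ``ga_coupling * z(GW) + sqrt(1-c^2) * noise`` so
    measures share the age trend, and PAD follows the linear generating
    model.  Returns (DataFrame, truth dict).
    """
    import pandas as pd

    spec = spec or CohortSpec()
    gamma = gamma if gamma is not None else {}
    rng = np.random.default_rng(seed)
    a = (spec.ga_range[0] - spec.ga_mean) / spec.ga_sd
    b = (spec.ga_range[1] - spec.ga_mean) / spec.ga_sd
    gw = truncnorm.rvs(a, b, loc=spec.ga_mean, scale=spec.ga_sd, size=n, random_state=rng)
    sex = _draw_sexes(n, spec.sex_ratio, rng)
    z_gw = (gw - gw.mean()) / gw.std()
    cols = {}
    for mname in measures:
        x = ga_coupling * z_gw + np.sqrt(1 - ga_coupling**2) * rng.standard_normal(n)
        cols[mname] = x
    pad = rng.normal(0.0, sigma_pad, size=n)
    for mname, g in gamma.items():
        x = cols[mname]
        pad = pad + g * (x - x.mean()) / x.std()
    if gamma_int != 0.0 and interaction_measure is not None:
        x = cols[interaction_measure]
        male = (sex == "M").astype(float)
        pad = pad + gamma_int * ((x - x.mean()) / x.std()) * male
    df = pd.DataFrame({"id": [f"s{i:03d}" for i in range(n)], "gw": gw, "sex": sex, "pad": pad})
    for mname, x in cols.items():
        df[mname] = x
    truth = {"gamma": dict(gamma), "gamma_int": gamma_int, "sigma_pad": sigma_pad}
    return df, truth


def synth_cohort(
    spec: CohortSpec | None = None,
    model: GrowthModel | None = None,
    spacing: float = 1.5,
    kernel_diameter: float = 15.0,
    measures: tuple[str, ...] = (
        "cerebral_volume",
        "surface_area",
        "mean_abs_curvature",
        "gyrification_index",
    ),
    keep_meshes: bool = False,
):
    """Mesh-based cohort: draw GA/sex, build surfaces, measure them, then
    generate PAD from the measured columns.  Returns (DataFrame, truth).

    ``measures`` selects which morphometry columns are computed (depth is
    the costly one and is opt-in: add "mean_sulcal_depth").
    """
    import pandas as pd

    from .geometry import enclosed_volume, mean_curvature, vertex_areas
    from .morphometry import gyrification_index, hull_surface, sulcal_depth

    spec = spec or CohortSpec()
    model = model or GrowthModel()
    rng = np.random.default_rng(spec.seed)
    a = (spec.ga_range[0] - spec.ga_mean) / spec.ga_sd
    b = (spec.ga_range[1] - spec.ga_mean) / spec.ga_sd
    gw = truncnorm.rvs(
        a, b, loc=spec.ga_mean, scale=spec.ga_sd, size=spec.n, random_state=rng
    )
    sex = _draw_sexes(spec.n, spec.sex_ratio, rng)

    need_voxels = {"gyrification_index", "mean_sulcal_depth"} & set(measures)
    rows = []
    meshes = []
    for i in range(spec.n):
        r_i = model.radius(gw[i]) + rng.normal(0.0, spec.radius_jitter)
        # fold wavelength and amplitude are both in absolute mm (the degree
        # band tracks the radius), so the folding steepness — hence GI —
        # varies only through amp_jitter and GA, independently of size jitter
        a_i = max(0.0, model.amplitude(gw[i]) + rng.normal(0.0, spec.amp_jitter))
        sub_seed = int(rng.integers(2**31 - 1))
        mesh, _ = synth_surface(
            gw[i], model, seed=sub_seed, radius=r_i, amplitude=a_i
        )
        row: dict[str, float] = {}
        if "cerebral_volume" in measures:
            row["cerebral_volume"] = enclosed_volume(mesh)
        if "surface_area" in measures:
            row["surface_area"] = mesh.area()
        if "mean_abs_curvature" in measures:
            areas = vertex_areas(mesh).values
            H = np.abs(mean_curvature(mesh).values)
            row["mean_abs_curvature"] = float(np.sum(areas * H) / areas.sum())
        if need_voxels:
            hull = hull_surface(mesh, spacing, kernel_diameter)
            if "gyrification_index" in measures:
                row["gyrification_index"] = gyrification_index(mesh, hull)
            if "mean_sulcal_depth" in measures:
                areas = vertex_areas(mesh).values
                dep = sulcal_depth(mesh, hull, spacing, kernel_diameter).values
                row["mean_sulcal_depth"] = float(np.sum(areas * dep) / areas.sum())
        rows.append(row)
        if keep_meshes:
            meshes.append(mesh)

    df = pd.DataFrame(rows)

    gz = (gw - gw.mean()) / gw.std()
    trend_basis = np.column_stack([np.ones(spec.n), gz, gz**2, gz**3])

    def _adjusted_z(x: np.ndarray) -> np.ndarray:
        # age-detrended z-score: the injected signal is the part of the
        # measure reflecting individual variation rather than gestational
        # age (cubic trend removed: volume is exactly cubic in GA).  Raw
        # z(X) would leak the smooth GA trend shared by *every* age-trended
        # measure into PAD, flagging measures that carry no signal.
        resid = x - trend_basis @ np.linalg.lstsq(trend_basis, x, rcond=None)[0]
        return resid / resid.std()

    pad = rng.normal(0.0, spec.sigma_pad, size=spec.n)
    for mname, g in spec.gamma.items():
        if mname not in df.columns:
            raise ValueError(f"PAD model references unmeasured column '{mname}'")
        pad = pad + g * _adjusted_z(df[mname].to_numpy())
    if spec.gamma_int != 0.0 and spec.interaction_measure is not None:
        male = (sex == "M").astype(float)
        pad = pad + spec.gamma_int * _adjusted_z(
            df[spec.interaction_measure].to_numpy()
        ) * male
    df.insert(0, "pad", pad)
    df.insert(0, "sex", sex)
    df.insert(0, "gw", gw)
    df.insert(0, "id", [f"s{i:03d}" for i in range(spec.n)])
    truth = {
        "gamma": dict(spec.gamma),
        "gamma_int": spec.gamma_int,
        "sigma_pad": spec.sigma_pad,
        "signal_measures": sorted(spec.gamma),
    }
    if keep_meshes:
        return df, truth, meshes
    return df, truth


def pattern_age_filter(df, lo: float = 23.0, hi: float = 32.0):
    """Restrict a cohort to the template age range for sulcal pattern
    analysis (templates exist for a limited GA band, so subjects outside
    it are excluded from similarity measurement)."""
    return df[(df["gw"] >= lo) & (df["gw"] <= hi)].reset_index(drop=True)


def synth_template(
    model: GrowthModel | None = None,
    ga: float = 29.0,
    seed: int = 12345,
    spacing: float = 1.5,
    smooth_iters: int = 10,
    merge_ridge: float = 0.02,
):
    """Canonical template surface + its sulcal basin graph at 29 GW.

    Subjects generated from perturbations of the template's harmonic
    coefficients deviate controllably from its pattern, so similarity to
    the template decreases with perturbation size.  Returns
    (mesh, basin_graph, coeffs).
    """
    from .pattern import build_basin_graph

    model = model or GrowthModel()
    rng = np.random.default_rng(seed)
    coeffs = sample_fold_coeffs(model, rng)
    mesh, _ = synth_surface(ga, model, coeffs=coeffs)
    graph = build_basin_graph(
        mesh, spacing=spacing, smooth_iters=smooth_iters, merge_ridge=merge_ridge
    )
    return mesh, graph, coeffs
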