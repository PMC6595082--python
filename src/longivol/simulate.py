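"""Synthetic inputs with known ground truth.

Real inputs to this pipeline are access-controlled clinical MRI derivatives
(hippocampus segmentations and registration deformation fields), so every
stage is exercised instead on synthetic data that emulate their relevant
properties:

* **shapes** — compact hippocampus-like 3-D bodies (digitized ellipsoids,
  optionally with a smooth radial perturbation) of 2000–4000 mm^3, a
  literature-typical adult hippocampal volume range;
* **deformation fields** — smooth invertible displacement fields with
  closed-form or fine-grid ground-truth regional volume change;
* **cohorts** — per-subject percentage-volume-change (PVC) tables with the
  study's structure: diagnostic groups (default 20 CTRL / 40 MCI / 20 AD),
  back-to-back A/B scan replicates, and left/right structures, with group
  means/SDs taken from a reference table of eight published measurement
  methods.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import BASELINE_TO_FOLLOWUP, DisplacementField
from .segmentation import LabelVolume
from .stats import CohortTable

log = logging.getLogger(__name__)

__all__ = [
    "ShapeSpec",
    "FieldSpec",
    "CohortSpec",
    "make_segmentation",
    "make_field",
    "simulate_cohort",
    "end_to_end_fixture",
    "REFERENCE_GROUP_STATS",
    "REFERENCE_REPRODUCIBILITY",
    "TRAINING_GROUP_STATS",
    "DEFAULT_GROUP_SIZES",
]

# ---------------------------------------------------------------------------
# Reference summary statistics of the eight measurement methods
# ---------------------------------------------------------------------------

#: One-year hippocampal PVC mean and SD (%) per diagnostic group, pooled A+B
#: scans, for eight measurement methods (manual outlining, three automatic
#: segmenters, four non-linear registration tools). These published summary
#: values parameterize the cohort generator and are the inputs of the
#: effect-size / sample-size reproduction.
REFERENCE_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "Manual":     {"CTRL": (-3.18, 3.838), "MCI": (-3.89, 3.813), "AD": (-4.81, 3.833)},
    "FSL-FIRST":  {"CTRL": (-1.88, 3.785), "MCI": (-3.00, 4.592), "AD": (-4.94, 4.506)},
    "FreeSurfer": {"CTRL": (-1.42, 2.650), "MCI": (-2.53, 3.335), "AD": (-4.47, 3.598)},
    "MALF":       {"CTRL": (-0.86, 2.121), "MCI": (-1.60, 2.737), "AD": (-1.88, 3.145)},
    "Elastix":    {"CTRL": (-1.08, 1.480), "MCI": (-1.60, 2.359), "AD": (-2.70, 1.665)},
    "NiftyReg":   {"CTRL": (-1.06, 1.516), "MCI": (-1.68, 2.719), "AD": (-3.25, 2.474)},
    "ANTs":       {"CTRL": (-2.27, 1.798), "MCI": (-2.90, 2.216), "AD": (-3.49, 1.941)},
    "MIRTK":      {"CTRL": (-1.30, 1.752), "MCI": (-2.32, 3.133), "AD": (-3.90, 2.599)},
}

#: Published A-vs-B test–retest distance D_Ave (%) per method; D_Ave/sqrt(2)
#: is the implied per-replicate noise SD under the additive-noise model.
REFERENCE_REPRODUCIBILITY: dict[str, float] = {
    "Manual": 12.39, "FSL-FIRST": 6.15, "FreeSurfer": 3.26, "MALF": 3.60,
    "Elastix": 1.78, "NiftyReg": 2.11, "ANTs": 1.06, "MIRTK": 3.76,
}

#: Two-year PVC means/SDs of the slow/fast extreme-trait training groups for
#: the four registration methods.
TRAINING_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "Elastix":  {"slow": (-1.36, 2.153), "fast": (-6.33, 5.448)},
    "NiftyReg": {"slow": (-1.96, 2.781), "fast": (-6.24, 4.154)},
    "ANTs":     {"slow": (-2.39, 1.721), "fast": (-4.66, 3.050)},
    "MIRTK":    {"slow": (-1.75, 2.218), "fast": (-7.32, 6.124)},
}

DEFAULT_GROUP_SIZES: dict[str, int] = {"CTRL": 20, "MCI": 40, "AD": 20}


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpec:
    """A compact hippocampus-like 3-D shape to digitize.

    ``perturb_amplitude`` modulates the ellipsoid radius by a smooth random
    fraction (0 = exact ellipsoid); ``perturb_smoothness`` is the Gaussian
    correlation length of that modulation in mm.
    """

    kind: str = "ellipsoid"  # "ellipsoid" | "perturbed_blob"
    semi_axes: tuple[float, float, float] = (12.0, 8.0, 6.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: float = 1.0
    perturb_amplitude: float = 0.0
    perturb_smoothness: float = 4.0
    seed: int = 0
    margin: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "perturbed_blob"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if min(self.semi_axes) <= 2 * self.spacing:
            raise ValueError("semi-axes must exceed twice the spacing")
        if not 0 <= self.perturb_amplitude < 0.5:
            raise ValueError("perturb_amplitude must lie in [0, 0.5)")

    @property
    def analytic_volume(self) -> float:
        """Closed-form ellipsoid volume (exact only when unperturbed)."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def with_spacing(self, spacing: float) -> "ShapeSpec":
        from dataclasses import replace
        return replace(self, spacing=spacing)


def _grid(spec: ShapeSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """Cell-centered grid covering the shape plus margin.

    Voxel centers are offset half a spacing from the shape's symmetry
    planes: sampling the analytic boundary exactly at voxel centers is a
    degenerate digitization with inflated surface error.
    """
    h = spec.spacing
    extents = np.asarray(spec.semi_axes) * (1 + spec.perturb_amplitude) + spec.margin
    n = np.ceil(2 * extents / h).astype(int)
    start = np.asarray(spec.center) - n * h / 2.0
    affine = np.eye(4)
    affine[:3, :3] = np.diag([h, h, h])
    affine[:3, 3] = start + h / 2.0  # index (0,0,0) -> first voxel center
    return tuple(int(x) for x in n), affine


def _radius_modulation(spec: ShapeSpec, shape: tuple[int, int, int]) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(shape)
    sigma_vox = spec.perturb_smoothness / spec.spacing
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.zeros(shape)
    return smooth / peak


def make_segmentation(spec: ShapeSpec) -> LabelVolume:
    """Digitize the shape: voxel-center indicator on a cell-centered grid."""
    shape, affine = _grid(spec)
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    pts = idx @ affine[:3, :3].T + affine[:3, 3]
    q = np.zeros(len(pts))
    for k in range(3):
        q += ((pts[:, k] - spec.center[k]) / spec.semi_axes[k]) ** 2
    q = q.reshape(shape)
    if spec.kind == "perturbed_blob" and spec.perturb_amplitude > 0:
        eta = _radius_modulation(spec, shape)
        inside = q <= (1.0 + spec.perturb_amplitude * eta) ** 2
    else:
        inside = q <= 1.0
    if not inside.any():
        raise ValueError("shape produced no foreground voxels")
    if inside[0].any() or inside[-1].any() or inside[:, 0].any() \
            or inside[:, -1].any() or inside[:, :, 0].any() or inside[:, :, -1].any():
        raise ValueError("shape exceeds grid: increase margin")
    return LabelVolume(inside.astype(np.uint8), affine)


# ---------------------------------------------------------------------------
# Deformation fields
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """An analytic displacement field with known regional volume change.

    Kinds and their parameters:

    - ``zero`` — no parameters; ground-truth PVC 0.
    - ``translation`` — ``translation`` (mm); PVC 0.
    - ``uniform_scale`` — ``scale`` = (sx, sy, sz) about ``center``;
      PVC = (sx·sy·sz − 1)·100 exactly.
    - ``radial_gaussian_contraction`` — u(x) = −k·exp(−r²/2σ²)·(x−c) with
      ``amplitude`` k < 0.9 (invertibility bound) and ``width`` σ (mm);
      ground truth by fine-grid quadrature of the analytic determinant.
    - ``smooth_random`` — superposition of ``n_bumps`` random Gaussian
      bumps with vector amplitudes; the summed gradient bound
      Σ|a_j|·e^{−1/2}/σ_j must stay below 0.5 for invertibility.
    """

    kind: str = "zero"
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    amplitude: float = 0.05
    width: float = 8.0
    n_bumps: int = 6
    bump_extent: float = 12.0
    seed: int = 0

    _KINDS = ("zero", "translation", "uniform_scale",
              "radial_gaussian_contraction", "smooth_random")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.kind == "radial_gaussian_contraction":
            if not 0 <= self.amplitude < 0.9:
                raise ValueError(
                    "radial contraction amplitude outside invertibility "
                    "bound [0, 0.9)")
            if self.width <= 0:
                raise ValueError("width must be positive")
        if self.kind == "uniform_scale" and min(self.scale) <= 0:
            raise ValueError("scale factors must be positive")

    # -- analytic field ----------------------------------------------------

    def _bumps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        centers = np.asarray(self.center) + rng.uniform(
            -self.bump_extent, self.bump_extent, size=(self.n_bumps, 3))
        sigmas = rng.uniform(0.8 * self.width, 1.2 * self.width, self.n_bumps)
        dirs = rng.standard_normal((self.n_bumps, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        amps = dirs * self.amplitude
        bound = float(np.sum(np.linalg.norm(amps, axis=1)
                             * np.exp(-0.5) / sigmas))
        if bound >= 0.5:
            raise ValueError(
                f"smooth_random parameters outside invertibility bound "
                f"(gradient bound {bound:.2f} >= 0.5)")
        return centers, sigmas, amps

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        """Evaluate u(x) analytically at (n, 3) world-mm points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center)
        if self.kind == "zero":
            return np.zeros_like(pts)
        if self.kind == "translation":
            return np.broadcast_to(np.asarray(self.translation), pts.shape).copy()
        if self.kind == "uniform_scale":
            s = np.asarray(self.scale)
            return (pts - c) * (s - 1.0)
        if self.kind == "radial_gaussian_contraction":
            d = pts - c
            r2 = np.sum(d * d, axis=1)
            e = np.exp(-r2 / (2 * self.width**2))
            return -self.amplitude * e[:, None] * d
        # smooth_random
        centers, sigmas, amps = self._bumps()
        u = np.zeros_like(pts)
        for cj, sj, aj in zip(centers, sigmas, amps):
            d = pts - cj
            e = np.exp(-np.sum(d * d, axis=1) / (2 * sj**2))
            u += e[:, None] * aj
        return u

    def jacobian_det(self, pts: np.ndarray) -> np.ndarray:
        """Analytic det(I + ∂u/∂x) at (n, 3) world-mm points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        n = len(pts)
        if self.kind in ("zero", "translation"):
            return np.ones(n)
        if self.kind == "uniform_scale":
            return np.full(n, float(np.prod(self.scale)))
        if self.kind == "radial_gaussian_contraction":
            k, s2 = self.amplitude, self.width**2
            d = pts - np.asarray(self.center)
            r2 = np.sum(d * d, axis=1)
            e = np.exp(-r2 / (2 * s2))
            # eigenvalues: tangential (1 - kE) twice, radial 1 - kE(1 - r^2/s^2)
            return (1 - k * e) ** 2 * (1 - k * e * (1 - r2 / s2))
        centers, sigmas, amps = self._bumps()
        jac = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
        for cj, sj, aj in zip(centers, sigmas, amps):
            d = pts - cj
            e = np.exp(-np.sum(d * d, axis=1) / (2 * sj**2))
            # d u_i / d x_k = a_i * E * (-(x_k - c_k) / sigma^2)
            jac += (e[:, None] / sj**2)[:, None] * \
                np.einsum("i,nk->nik", np.asarray(aj), -d)
        return np.linalg.det(jac)

    @property
    def analytic_pvc(self) -> float | None:
        """Closed-form PVC (%) where it exists, else None."""
        if self.kind in ("zero", "translation"):
            return 0.0
        if self.kind == "uniform_scale":
            return float((np.prod(self.scale) - 1.0) * 100.0)
        return None


def _ground_truth_pvc(spec: FieldSpec, seg: LabelVolume,
                      shape: ShapeSpec | None, refine: int = 4) -> float:
    """Regional PVC: analytic where closed-form, else fine-grid quadrature.

    The quadrature averages the analytic Jacobian determinant over a
    ``refine``-times finer digitization of the shape (analytic indicator
    when a :class:`ShapeSpec` is given, sub-sampled mask voxels otherwise).
    """
    closed = spec.analytic_pvc
    if closed is not None:
        return closed
    if shape is not None:
        fine = make_segmentation(shape.with_spacing(shape.spacing / refine))
        idx = np.argwhere(fine.data > 0).astype(float)
        pts = fine.voxel_to_world(idx)
    else:
        # subdivide each foreground voxel of seg into refine^3 sample points
        idx = np.argwhere(seg.data > 0).astype(float)
        offs = (np.indices((refine,) * 3).reshape(3, -1).T + 0.5) / refine - 0.5
        sub = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        pts = seg.voxel_to_world(sub)
    det = spec.jacobian_det(pts)
    return float((det.mean() - 1.0) * 100.0)


def make_field(
    spec: FieldSpec,
    grid_from: LabelVolume,
    shape: ShapeSpec | None = None,
    ground_truth: bool = True,
) -> tuple[DisplacementField, float | None]:
    """Sample the analytic field on a label volume's grid.

    Returns the dense baseline→follow-up :class:`DisplacementField` together
    with the ground-truth regional PVC (%) for the generating shape
    (``None`` when ``ground_truth`` is disabled to skip the fine-grid
    quadrature).
    """
    shp = grid_from.data.shape
    idx = np.indices(shp, dtype=float).reshape(3, -1).T
    pts = grid_from.voxel_to_world(idx)
    u = spec.displacement(pts).reshape(shp + (3,))
    fld = DisplacementField(u, affine=grid_from.affine.copy(),
                           direction=BASELINE_TO_FOLLOWUP)
    truth = _ground_truth_pvc(spec, grid_from, shape) if ground_truth else None
    return fld, truth


def end_to_end_fixture(
    shape: ShapeSpec, field: FieldSpec
) -> tuple[LabelVolume, DisplacementField, float]:
    """Bundle (segmentation, displacement field, expected PVC) for one case."""
    seg = make_segmentation(shape)
    fld, truth = make_field(field, seg, shape=shape)
    return seg, fld, truth


def default_fixture_suite(n: int = 10, spacing: float = 1.0,
                          base_seed: int = 0) -> list[tuple[ShapeSpec, FieldSpec]]:
    """A standard battery of (shape, smooth field) route-equivalence cases.

    Mixes plain and perturbed shapes with radial contractions, random smooth
    fields and uniform scalings; deterministic given ``base_seed``.
    """
    cases = []
    for i in range(n):
        seed = base_seed * 1000 + i
        shape = ShapeSpec(
            kind="perturbed_blob" if i % 2 else "ellipsoid",
            semi_axes=(12.0 - 0.3 * (i % 5), 8.0 + 0.2 * (i % 4), 6.0 + 0.1 * i),
            perturb_amplitude=0.08 if i % 2 else 0.0,
            spacing=spacing, seed=seed)
        k = i % 3
        if k == 0:
            fld = FieldSpec(kind="radial_gaussian_contraction",
                            amplitude=0.03 + 0.005 * i, width=7.0 + 0.5 * i,
                            seed=seed)
        elif k == 1:
            fld = FieldSpec(kind="smooth_random", amplitude=0.4, width=9.0,
                            n_bumps=6, seed=seed)
        else:
            fld = FieldSpec(kind="uniform_scale",
                            scale=(0.983 + 0.002 * (i % 4),) * 3)
        cases.append((shape, fld))
    return cases


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _default_replicate_sd(method: str,
                          group_stats: dict[str, tuple[float, float]]) -> float:
    """Per-replicate noise SD implied by the method's published D_Ave.

    sigma_eps = D_Ave/sqrt(2) under additive i.i.d. replicate noise, capped
    at 90% of the smallest group SD so the variance partition stays valid
    (for poorly reproducible methods the additive-Gaussian model cannot
    attain the published D_Ave without exceeding the group spread).
    """
    min_sd = min(sd for _, sd in group_stats.values())
    cap = 0.9 * min_sd
    if method in REFERENCE_REPRODUCIBILITY:
        return min(REFERENCE_REPRODUCIBILITY[method] / np.sqrt(2.0), cap)
    return min(1.5, cap)


@dataclass
class CohortSpec:
    """Generative model of a back-to-back-scan atrophy cohort.

    Per subject i in group g: a true PVC v_i ~ N(μ_g, σ_true) with
    σ_true² = σ_g² − σ_ε², observed once per scan replicate as
    v_i + ε (ε ~ N(0, σ_ε)), then split antisymmetrically into left/right
    as (value + δ, value − δ) with δ ~ N(0, σ_side) so the side average is
    the subject value and the pooled group SD matches σ_g by construction.
    """

    method: str = "FreeSurfer"
    group_sizes: dict[str, int] = dc_field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    group_stats: dict[str, tuple[float, float]] | None = None
    replicate_sd: float | None = None  # sigma_eps; None -> method default
    side_sd: float = 0.5
    outlier_rate: float = 0.0
    v_bl_range: tuple[float, float] = (1000.0, 2000.0)  # per side, mm^3
    threshold: float = 25.0
    seed: int = 0

    def resolved_stats(self) -> dict[str, tuple[float, float]]:
        if self.group_stats is not None:
            return self.group_stats
        if self.method in REFERENCE_GROUP_STATS:
            return REFERENCE_GROUP_STATS[self.method]
        if self.method in TRAINING_GROUP_STATS:
            return TRAINING_GROUP_STATS[self.method]
        raise ValueError(f"no reference statistics for method {self.method!r}; "
                         "pass group_stats explicitly")

    def resolved_replicate_sd(self) -> float:
        if self.replicate_sd is not None:
            return self.replicate_sd
        return _default_replicate_sd(self.method, self.resolved_stats())

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("need at least 2 subjects per group")
        if self.side_sd < 0 or not 0 <= self.outlier_rate < 1:
            raise ValueError("invalid side_sd or outlier_rate")


def simulate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a full cohort PVC table (one method) from the generative model.

    Raises
    ------
    ValueError
        "replicate noise exceeds group SD" when σ_ε > σ_g for any group.
    """
    stats = spec.resolved_stats()
    sigma_e = spec.resolved_replicate_sd()
    for g, (_, sd) in stats.items():
        if sigma_e > sd:
            raise ValueError(
                f"replicate noise exceeds group SD: sigma_eps={sigma_e:.3g} "
                f"> sigma_{g}={sd:.3g}")
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for group in spec.group_sizes:  # insertion order: deterministic
        mu, sd = stats[group]
        sigma_true = float(np.sqrt(max(sd**2 - sigma_e**2, 0.0)))
        for _ in range(spec.group_sizes[group]):
            sid += 1
            subject = f"S{sid:03d}"
            v_true = rng.normal(mu, sigma_true)
            v_bl = {s: rng.uniform(*spec.v_bl_range) for s in ("L", "R")}
            for scan in ("A", "B"):
                obs = v_true + rng.normal(0.0, sigma_e)
                if spec.outlier_rate > 0 and rng.uniform() < spec.outlier_rate:
                    obs = rng.choice([-1.0, 1.0]) * rng.uniform(
                        spec.threshold + 5.0, 60.0)
                delta = rng.normal(0.0, spec.side_sd)
                for side, sign in (("L", 1.0), ("R", -1.0)):
                    p = obs + sign * delta
                    vb = v_bl[side]
                    rows.append({
                        "subject": subject, "group": group, "scan": scan,
                        "side": side, "method": spec.method,
                        "v_bl": vb, "v_fu": vb * (1.0 + p / 100.0),
                        "pvc": p,
                        "excluded": abs(p) > spec.threshold,
                        "exclude_reason": (f"|pvc|>{spec.threshold:g}"
                                           if abs(p) > spec.threshold else ""),
                    })
    df = pd.DataFrame(rows)
    return CohortTable(df, threshold=spec.threshold, provenance={
        "method": spec.method, "dataset": "simulated", "seed": spec.seed,
        "replicate_sd": sigma_e,
    })
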