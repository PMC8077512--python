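"""Synthetic-embryo ground truth for the translation-imaging pipeline.

Real inputs to the pipeline are 3D spot and nucleus tables measured from
confocal stacks of syncytial blastoderm embryos.  No such stacks ship with
the package, so this module generates statistically matched stand-ins with
known truth labels:

* nuclei on a jittered hexagonal monolayer lattice, clipped to an elliptical
  embryo outline whose anterior tip sits inside the imaging frame;
* cytoplasmic mRNAs per nuclear territory drawn from an AP expression
  profile, each translated with an AP-dependent probability;
* nascent-protein puncta colocated with translated mRNAs, whose intensity is
  (ribosome count x single-protein brightness x partial-epitope correction)
  with multiplicative noise, plus free single proteins and rare bright
  aggregates;
* 5'/3' probe-pair channels separated by a compaction distance that depends
  on translating status;
* rendered 3D image stacks and time-lapse series for tethered sites.

Each generator draws from its own seeded substream, so outputs are
deterministic and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import EmbryoConfig
from .io import make_spot_table, spot_xyz, write_nuclei, write_spots

MRNA = "mrna"
PROTEIN = "protein"
PROBE5 = "probe5"
PROBE3 = "probe3"

# seeded-substream indices, one per generator stage
_STAGE_NUCLEI, _STAGE_SPOTS, _STAGE_PROBES, _STAGE_TIMELAPSE, _STAGE_RENDER = range(5)


def _stage_rng(config: EmbryoConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.rng_seed), stage])


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with median 1 and coefficient of variation ~cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Embryo outline and true axis
# ---------------------------------------------------------------------------


@dataclass
class AxisTruth:
    """True embryo midline: anterior tip and unit direction pointing posterior."""

    tip_xy: np.ndarray
    direction_xy: np.ndarray
    semi_major: float
    semi_minor: float

    @property
    def center_xy(self) -> np.ndarray:
        return self.tip_xy + self.direction_xy * self.semi_major

    def ap_of(self, points: np.ndarray) -> np.ndarray:
        """AP position (µm from the anterior tip) of (n, 2|3) points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points[:, :2] - self.tip_xy) @ self.direction_xy

    def inside(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = points[:, :2] - self.center_xy
        perp = np.array([-self.direction_xy[1], self.direction_xy[0]])
        s = d @ self.direction_xy
        t = d @ perp
        return (s / self.semi_major) ** 2 + (t / self.semi_minor) ** 2 <= 1.0


def _axis_truth(config: EmbryoConfig) -> AxisTruth:
    theta = np.deg2rad(config.orientation_deg)
    u = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-u[1], u[0]])
    fx, fy, _ = config.frame_size
    c0 = np.array([fx / 2.0, fy / 2.0])
    # march from the frame centre against the axis until the frame boundary,
    # then step back in by the tip margin: the anterior tip lies in-frame
    with np.errstate(divide="ignore"):
        tx = np.where(u[0] > 0, c0[0] / u[0], (c0[0] - fx) / u[0]) if u[0] != 0 else np.inf
        ty = np.where(u[1] > 0, c0[1] / u[1], (c0[1] - fy) / u[1]) if u[1] != 0 else np.inf
    t_exit = float(min(tx, ty))
    tip = c0 - u * (t_exit - config.anterior_tip_margin) + perp * config.midline_offset_um
    return AxisTruth(
        tip_xy=tip,
        direction_xy=u,
        semi_major=config.embryo_length_el / 2.0,
        semi_minor=config.embryo_width / 2.0,
    )


def _visible_area(config: EmbryoConfig, axis: AxisTruth, step: float = 1.0) -> float:
    """Area (µm^2) of embryo-outline / frame intersection, by grid quadrature."""
    fx, fy, _ = config.frame_size
    xs = np.arange(step / 2, fx, step)
    ys = np.arange(step / 2, fy, step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return float(axis.inside(pts).sum()) * step * step


# ---------------------------------------------------------------------------
# Nuclei
# ---------------------------------------------------------------------------


def generate_nuclei(config: EmbryoConfig) -> tuple[pd.DataFrame, AxisTruth]:
    """Place nuclei on a jittered hexagonal monolayer inside the embryo outline.

    The lattice constant is set from the visible embryo area and ``n_nuclei``
    (hexagonal packing density), so the realized count approximates the
    configured one.  Raises ``ValueError`` when the requested density packs
    nuclei closer than their diameters.
    """
    axis = _axis_truth(config)
    fx, fy, fz = config.frame_size
    if config.n_nuclei == 0:
        empty = pd.DataFrame(
            {
                "id": pd.Series(dtype=int),
                "x_um": pd.Series(dtype=float),
                "y_um": pd.Series(dtype=float),
                "z_um": pd.Series(dtype=float),
                "radius_um": pd.Series(dtype=float),
                "frame": pd.Series(dtype=int),
            }
        )
        return empty, axis

    area = _visible_area(config, axis)
    spacing = float(np.sqrt(2.0 * area / (np.sqrt(3.0) * config.n_nuclei)))
    if spacing < 2.05 * config.nucleus_radius:
        raise ValueError(
            f"infeasible packing: {config.n_nuclei} nuclei of radius "
            f"{config.nucleus_radius} µm need spacing >= "
            f"{2.05 * config.nucleus_radius:.2f} µm but density gives {spacing:.2f} µm"
        )

    rng = _stage_rng(config, _STAGE_NUCLEI)
    row_h = spacing * np.sqrt(3.0) / 2.0
    phase = rng.uniform(0.0, spacing, size=2)
    rows = np.arange(-1, int(np.ceil(fy / row_h)) + 2)
    cols = np.arange(-1, int(np.ceil(fx / spacing)) + 2)
    cc, rr = np.meshgrid(cols, rows)
    x = cc * spacing + (rr % 2) * spacing / 2.0 + phase[0]
    y = rr * row_h + phase[1]
    pts = np.column_stack([x.ravel(), y.ravel()])
    if config.internuclear_jitter > 0:
        pts = pts + rng.normal(0.0, config.internuclear_jitter, size=pts.shape)

    keep = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= fx)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= fy)
        & axis.inside(pts)
    )
    pts = pts[keep]
    z = np.clip(
        fz / 2.0 + rng.normal(0.0, config.z_jitter, size=len(pts)),
        config.nucleus_radius if fz > 2 * config.nucleus_radius else 0.0,
        fz - config.nucleus_radius if fz > 2 * config.nucleus_radius else fz,
    )
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    nuclei = pd.DataFrame(
        {
            "id": np.arange(keep.sum()),
            "x_um": pts[order, 0],
            "y_um": pts[order, 1],
            "z_um": z[order],
            "radius_um": config.nucleus_radius,
            "frame": 0,
        }
    )
    return nuclei, axis


# ---------------------------------------------------------------------------
# Spots
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Synthetic embryo: nucleus table, per-channel spot tables, truth labels."""

    config: EmbryoConfig
    nuclei: pd.DataFrame
    spots: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    axis_truth: AxisTruth

    @property
    def cytoplasmic_truth(self) -> pd.DataFrame:
        return self.truth[~self.truth["nuclear"]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_nuclei(self.nuclei, outdir / "nuclei.tsv")
        for channel, table in self.spots.items():
            write_spots(table, outdir / f"spots_{channel}.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(outdir / "config.yaml")


def correction_factor_of(config: EmbryoConfig) -> float:
    """Partial-epitope correction (0.5*L_sun + L_hb) / (L_sun + L_hb)."""
    return (0.5 * config.length_suntag_nt + config.length_hb_nt) / (
        config.length_suntag_nt + config.length_hb_nt
    )


def _territory_radius(nuclei: pd.DataFrame) -> float:
    xy = nuclei[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) < 2:
        return 5.0
    d, _ = cKDTree(xy).query(xy, k=2)
    return 0.5 * float(np.median(d[:, 1]))


def generate_spots(config: EmbryoConfig, nuclei: pd.DataFrame, axis_truth: AxisTruth) -> GroundTruth:
    """Draw mRNA and nascent-protein channels with per-mRNA truth labels.

    mRNA counts per territory follow the AP expression profile; translation
    is Bernoulli in the AP translated-probability profile; translated mRNAs
    carry a nascent-protein punctum offset by an isotropic Gaussian of width
    ``coloc_sigma``.  A configured fraction of mRNAs is placed inside the
    nucleus sphere to exercise nuclear masking downstream.
    """
    rng = _stage_rng(config, _STAGE_SPOTS)
    fx, fy, fz = config.frame_size
    nuc_xy = nuclei[["x_um", "y_um"]].to_numpy(dtype=float)
    nuc_xyz = spot_xyz(nuclei)
    c_factor = correction_factor_of(config)

    if len(nuclei) == 0:
        n_mrna = 0
        nucleus_of = np.zeros(0, dtype=int)
    else:
        ap_nuc = axis_truth.ap_of(nuc_xy)
        lam = np.clip(np.asarray(config.expression_profile(ap_nuc), dtype=float), 0.0, None)
        counts = rng.poisson(lam)
        nucleus_of = np.repeat(nuclei["id"].to_numpy(), counts)
        n_mrna = int(counts.sum())

    terr_r = _territory_radius(nuclei)
    nuc_tree = cKDTree(nuc_xyz) if len(nuclei) else None
    radius = float(nuclei["radius_um"].max()) if len(nuclei) else 0.0

    # nuclear vs cytoplasmic placement
    nuclear = rng.random(n_mrna) < config.nuclear_fraction
    pos = np.zeros((n_mrna, 3))
    centers = nuc_xyz[
        pd.Index(nuclei["id"]).get_indexer(nucleus_of)
    ] if n_mrna else np.zeros((0, 3))

    # inside the nucleus: uniform within 0.9 of the sphere radius
    idx_nuc = np.flatnonzero(nuclear)
    if len(idx_nuc):
        direc = rng.normal(size=(len(idx_nuc), 3))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        r = 0.9 * radius * rng.random(len(idx_nuc)) ** (1.0 / 3.0)
        pos[idx_nuc] = centers[idx_nuc] + direc * r[:, None]

    # cytoplasmic: uniform in the territory disc, rejected out of all nuclei
    idx_cyto = np.flatnonzero(~nuclear)
    todo = idx_cyto.copy()
    for _ in range(60):
        if not len(todo):
            break
        ang = rng.uniform(0.0, 2 * np.pi, size=len(todo))
        rad = terr_r * np.sqrt(rng.random(len(todo)))
        dz = rng.uniform(-2.0, 2.0, size=len(todo))
        cand = centers[todo] + np.column_stack(
            [rad * np.cos(ang), rad * np.sin(ang), dz]
        )
        cand[:, 2] = np.clip(cand[:, 2], 0.2, fz - 0.2)
        d_near, _ = nuc_tree.query(cand)
        ok = d_near > radius + 0.05
        pos[todo[ok]] = cand[ok]
        todo = todo[~ok]
    if len(todo):  # pathological config: fall back to territory boundary
        direc = rng.normal(size=(len(todo), 2))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        pos[todo] = centers[todo] + np.column_stack(
            [direc * (radius + 0.5), np.zeros(len(todo))]
        )

    ap_mrna = axis_truth.ap_of(pos) if n_mrna else np.zeros(0)
    p_tr = np.clip(np.asarray(config.translated_profile(ap_mrna), dtype=float), 0.0, 1.0)
    translated = rng.random(n_mrna) < p_tr

    ribosomes = np.zeros(n_mrna, dtype=int)
    n_sites = int(translated.sum())
    if n_sites:
        loads = rng.poisson(config.ribosome_load_mean, size=n_sites)
        loads[loads == 0] = 1  # a translation site has at least one ribosome
        ribosomes[translated] = loads

    mrna_int = config.mrna_intensity * _lognormal_factor(rng, config.mrna_cv, n_mrna)
    mrna = make_spot_table(pos, mrna_int, MRNA)

    # --- protein channel ---------------------------------------------------
    site_pos = pos[translated] + rng.normal(0.0, config.coloc_sigma, size=(n_sites, 3))
    site_int = (
        ribosomes[translated]
        * config.single_protein_intensity
        * c_factor
        * _lognormal_factor(rng, config.intensity_cv, n_sites)
    )

    volume = fx * fy * fz
    n_free = rng.poisson(config.free_protein_density * volume)
    free_pos = rng.uniform([0, 0, 0], [fx, fy, fz], size=(n_free, 3))
    free_int = config.single_protein_intensity * _lognormal_factor(
        rng, config.single_protein_cv, n_free
    )

    n_agg = rng.poisson(config.aggregate_density * volume)
    agg_pos = rng.uniform([0, 0, 0], [fx, fy, fz], size=(n_agg, 3))
    agg_int = (
        config.aggregate_brightness_factor
        * config.single_protein_intensity
        * _lognormal_factor(rng, 0.3, n_agg)
    )

    prot_pos = np.concatenate([site_pos, free_pos, agg_pos]) if (
        n_sites + n_free + n_agg
    ) else np.zeros((0, 3))
    prot_int = np.concatenate([site_int, free_int, agg_int])
    protein = make_spot_table(prot_pos, prot_int, PROTEIN)
    protein_kind = np.array(
        ["site"] * n_sites + ["single"] * n_free + ["aggregate"] * n_agg
    )

    protein_id = np.full(n_mrna, -1, dtype=int)
    protein_id[translated] = np.arange(n_sites)

    # territory truth label: nearest nucleus in 3D, matching the pipeline rule
    if len(nuclei) and n_mrna:
        _, near = nuc_tree.query(pos)
        truth_nucleus = nuclei["id"].to_numpy()[near]
    else:
        truth_nucleus = nucleus_of

    truth = pd.DataFrame(
        {
            "mrna_id": np.arange(n_mrna),
            "nucleus_id": truth_nucleus,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "ap_true_um": ap_mrna,
            "nuclear": nuclear,
            "translated": translated,
            "ribosomes": ribosomes,
            "protein_id": protein_id,
        }
    )
    spots = {MRNA: mrna, PROTEIN: protein}
    gt = GroundTruth(config=config, nuclei=nuclei, spots=spots, truth=truth, axis_truth=axis_truth)
    gt.protein_kind = protein_kind  # per-protein-spot truth class
    return gt


def generate_embryo(config: EmbryoConfig) -> GroundTruth:
    """Convenience: nuclei + spot channels in one call."""
    nuclei, axis = generate_nuclei(config)
    return generate_spots(config, nuclei, axis)


# ---------------------------------------------------------------------------
# 5'/3' probe pairs
# ---------------------------------------------------------------------------


@dataclass
class ProbePairTruth:
    five: pd.DataFrame
    three: pd.DataFrame
    pairs: pd.DataFrame  # mrna_id, distance_um, translating


def generate_probe_pairs(config: EmbryoConfig, gt: GroundTruth) -> ProbePairTruth:
    """Dual-probe channels: 5' at the mRNA, 3' displaced by a compaction distance.

    Separations are lognormal with medians conditioned on translating status
    (translating mRNAs slightly more open).  A configurable density of
    3'-only spots emulates probes hybridizing to untagged endogenous mRNAs.
    """
    rng = _stage_rng(config, _STAGE_PROBES)
    truth = gt.truth
    n = len(truth)
    pos5 = truth[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    median = np.where(
        truth["translated"].to_numpy(),
        config.translating_compaction_median,
        config.nontranslating_compaction_median,
    )
    # lognormal about the class median; a zero median is a point mass at 0
    safe = np.where(median > 0, median, 1.0)
    dist = np.exp(np.log(safe) + config.compaction_sigma * rng.standard_normal(n))
    dist = np.where(median > 0, dist, 0.0)
    direc = rng.normal(size=(n, 3))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    pos3 = pos5 + direc * dist[:, None]

    fx, fy, fz = config.frame_size
    n_extra = rng.poisson(config.extra_3p_density * fx * fy * fz)
    extra = rng.uniform([0, 0, 0], [fx, fy, fz], size=(n_extra, 3))

    int5 = config.mrna_intensity * _lognormal_factor(rng, config.mrna_cv, n)
    int3 = config.mrna_intensity * _lognormal_factor(rng, config.mrna_cv, n + n_extra)
    five = make_spot_table(pos5, int5, PROBE5, ids=truth["mrna_id"].to_numpy())
    three = make_spot_table(np.concatenate([pos3, extra]) if n + n_extra else np.zeros((0, 3)),
                            int3, PROBE3)
    pairs = pd.DataFrame(
        {
            "mrna_id": truth["mrna_id"].to_numpy(),
            "distance_um": dist,
            "translating": truth["translated"].to_numpy(),
        }
    )
    return ProbePairTruth(five=five, three=three, pairs=pairs)


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Camera model for rendered stacks: Poisson shot noise on signal plus
    background, then zero-mean Gaussian read noise."""

    background: float = 20.0
    read_sigma: float = 2.0
    poisson: bool = True
    seed: int = 0


def _axis_profile(centers: np.ndarray, sigma: float, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel integrals of a unit 1D Gaussian, over a clipped window."""
    from scipy.special import erf

    lo = np.maximum(0, np.floor(centers - 4 * sigma - 1).astype(int))
    hi = np.minimum(size, np.ceil(centers + 4 * sigma + 2).astype(int))
    return lo, hi


def render_spots(
    spots: pd.DataFrame,
    frame_size: tuple[float, float, float],
    voxel_size: tuple[float, float, float] = (0.12, 0.12, 0.3),
    psf_sigma_xy: float = 0.15,
    psf_sigma_z: float = 0.35,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """Render a spot table into a (z, y, x) stack of anisotropic Gaussians.

    Each spot's *integrated* (per-voxel-summed) intensity equals its table
    intensity up to boundary clipping; per-voxel values use exact erf
    integration of the Gaussian over the voxel.
    """
    from scipy.special import erf

    vx, vy, vz = voxel_size
    fx, fy, fz = frame_size
    shape = (max(1, int(np.ceil(fz / vz))), max(1, int(np.ceil(fy / vy))),
             max(1, int(np.ceil(fx / vx))))
    if any(s > 4096 for s in shape):
        raise ValueError(f"voxel grid {shape} overflows a sane stack size")
    img = np.zeros(shape, dtype=float)

    cx = spots["x_um"].to_numpy(dtype=float) / vx
    cy = spots["y_um"].to_numpy(dtype=float) / vy
    cz = spots["z_um"].to_numpy(dtype=float) / vz
    sx, sy, sz = psf_sigma_xy / vx, psf_sigma_xy / vy, psf_sigma_z / vz
    inten = spots["intensity"].to_numpy(dtype=float)

    for i in range(len(spots)):
        profs = []
        idxs = []
        for c, s, size in ((cz[i], sz, shape[0]), (cy[i], sy, shape[1]), (cx[i], sx, shape[2])):
            lo = max(0, int(np.floor(c - 4 * s - 1)))
            hi = min(size, int(np.ceil(c + 4 * s + 2)))
            if hi <= lo:
                profs = None
                break
            edges = np.arange(lo, hi + 1, dtype=float)
            cdf = 0.5 * (1.0 + erf((edges - c) / (np.sqrt(2.0) * s)))
            profs.append(np.diff(cdf))
            idxs.append((lo, hi))
        if profs is None:
            continue
        pz, py, px = profs
        (z0, z1), (y0, y1), (x0, x1) = idxs
        img[z0:z1, y0:y1, x0:x1] += inten[i] * pz[:, None, None] * py[None, :, None] * px[None, None, :]

    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        base = img + noise.background
        out = rng.poisson(np.clip(base, 0, None)).astype(float) if noise.poisson else base
        if noise.read_sigma > 0:
            out = out + rng.normal(0.0, noise.read_sigma, size=shape)
        return out
    return img


def write_stack(image: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), image.astype(np.float32))


# ---------------------------------------------------------------------------
# Time-lapse
# ---------------------------------------------------------------------------


@dataclass
class TimelapseTruth:
    """Per-frame detections of membrane-tethered translation sites.

    ``sites`` carries a truth ``track_id`` per detection; free single
    proteins diffuse with the configured coefficient and share the table
    with sites (track ids offset by 100000).
    """

    config: EmbryoConfig
    sites: pd.DataFrame
    nuclei: pd.DataFrame
    anchors: pd.DataFrame


def generate_timelapse(config: EmbryoConfig) -> TimelapseTruth:
    """Tethered sites jitter about fixed anchors; free proteins diffuse;
    per-frame dropout removes detections at the configured rate."""
    rng = _stage_rng(config, _STAGE_TIMELAPSE)
    nuclei0, axis = generate_nuclei(config)
    fx, fy, fz = config.frame_size
    dt = config.frame_interval_s
    c_factor = correction_factor_of(config)

    # anchors uniform in the visible embryo region
    anchors = np.zeros((0, 2))
    while len(anchors) < config.n_tethered_sites:
        cand = rng.uniform([0, 0], [fx, fy], size=(4 * config.n_tethered_sites, 2))
        cand = cand[axis.inside(cand)]
        anchors = np.concatenate([anchors, cand])[: config.n_tethered_sites]
    z0 = fz / 2.0
    base_int = (
        config.ribosome_load_mean
        * config.single_protein_intensity
        * c_factor
        * _lognormal_factor(rng, 0.3, config.n_tethered_sites)
    )

    n_free = rng.poisson(config.free_protein_density * fx * fy * fz)
    free_pos = rng.uniform([0, 0], [fx, fy], size=(n_free, 2))
    step_sd = np.sqrt(2.0 * config.diffusion_coeff * dt)

    rows = []
    nuc_frames = []
    for f in range(config.n_frames):
        # tethered sites
        jit = rng.normal(0.0, config.site_jitter, size=(config.n_tethered_sites, 2))
        present = rng.random(config.n_tethered_sites) >= config.dropout_rate
        inten = base_int * _lognormal_factor(rng, config.intensity_cv, config.n_tethered_sites)
        for k in np.flatnonzero(present):
            rows.append((f, k, anchors[k, 0] + jit[k, 0], anchors[k, 1] + jit[k, 1], z0, inten[k]))
        # diffusing free proteins (reflected at the frame boundary)
        if n_free:
            free_pos = free_pos + rng.normal(0.0, step_sd, size=free_pos.shape)
            free_pos = np.abs(free_pos)
            free_pos[:, 0] = fx - np.abs(fx - free_pos[:, 0])
            free_pos[:, 1] = fy - np.abs(fy - free_pos[:, 1])
            present_free = rng.random(n_free) >= config.dropout_rate
            ints_free = config.single_protein_intensity * _lognormal_factor(
                rng, config.single_protein_cv, n_free
            )
            for k in np.flatnonzero(present_free):
                rows.append((f, 100000 + k, free_pos[k, 0], free_pos[k, 1], z0, ints_free[k]))
        nf = nuclei0.copy()
        nf["frame"] = f
        nuc_frames.append(nf)

    sites = pd.DataFrame(rows, columns=["frame", "track_id", "x_um", "y_um", "z_um", "intensity"])
    sites.insert(0, "id", np.arange(len(sites)))
    sites["channel"] = PROTEIN
    sites = sites[["id", "channel", "x_um", "y_um", "z_um", "intensity", "frame", "track_id"]]
    anchors_df = pd.DataFrame(
        {"track_id": np.arange(config.n_tethered_sites), "x_um": anchors[:, 0],
         "y_um": anchors[:, 1], "z_um": z0, "intensity": base_int}
    )
    nuclei_all = pd.concat(nuc_frames, ignore_index=True) if nuc_frames else nuclei0
    return TimelapseTruth(config=config, sites=sites, nuclei=nuclei_all, anchors=anchors_df)
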