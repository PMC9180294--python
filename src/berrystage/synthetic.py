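"""Synthetic-data generators emulating the two-stage strawberry study.

Every input modality the pipeline consumes can be generated with the
statistical structure the analysis assumes: e-nose plateau levels matched
to per-stage quantile summaries with sample-level replicate nesting; FTIR
spectra as Gaussian bands with stage-dependent amplitudes plus baseline and
multiplicative-scatter artefacts; berry images with controllable red/green
surface fractions and exact ground-truth masks; and a chemistry/VOC panel
with the documented correlation structure (TA/TP/AA co-vary positively,
TSS opposes them; most VOCs rise with ripening while 2-methylbutanoic acid
"Ac4" and mesifurane "F1" carry distinct, weaker stage structure).

All outputs are a deterministic function of the design seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import QuantileSpec, StudyDesign
from .enose import SensorTrace, write_trace_csv
from .ftir import DEFAULT_GRID, SpectraSet, write_spectra_csv
from .reference import SENSOR_NAMES, SENSOR_QUANTILES

#: Fraction of total (stage-level) variance carried by technical-replicate
#: noise; the sample-level random intercept carries the remainder.  Encodes
#: that technical-replicate scatter is much smaller than the biological
#: (between-sample) variability.
REPLICATE_VARIANCE_FRACTION = 0.10

#: Default red surface fraction per maturity stage (half-red fruit are 50%
#: red by definition; red fruit fully coloured).
STAGE_RED_FRACTION = {"half-red": 0.5, "red": 1.0}

#: Per-berry jitter (sd) applied to the target red fraction.
RED_FRACTION_JITTER = 0.03

# ---------------------------------------------------------------------------
# quantile-matched sampling
# ---------------------------------------------------------------------------


def sample_from_quantiles(spec: QuantileSpec, z: np.ndarray) -> np.ndarray:
    """Map standard-normal draws to values matching a QuantileSpec.

    The map uses side-specific scales (median-p5)/1.645 below the median
    and (p95-median)/1.645 above it, so an asymmetric printed summary keeps
    its median; draws are then clipped (censored) to [p5, p95].  Clipping
    parks the ~5% tail mass on the interval edges, so for large n the
    empirical median and 5th/95th percentiles reproduce the spec while the
    support never leaves [p5, p95] — printed ranges that are disjoint
    between stages stay disjoint in the generated data.  For a symmetric
    spec the base distribution is N(median, (p95-p5)/3.29).
    """
    z = np.asarray(z, float)
    lo_scale = (spec.median - spec.p5) / 1.645
    hi_scale = (spec.p95 - spec.median) / 1.645
    x = spec.median + np.where(z < 0, z * lo_scale, z * hi_scale)
    return np.clip(x, spec.p5, spec.p95)


def nested_normals(
    rng: np.random.Generator,
    n_samples: int,
    n_reps: int,
    replicate_fraction: float = REPLICATE_VARIANCE_FRACTION,
) -> np.ndarray:
    """Unit-variance draws with a sample-level random intercept.

    Returns an (n_samples, n_reps) array z = a_s + e_sr with
    Var(e_sr) = replicate_fraction and Var(a_s) = 1 - replicate_fraction,
    so biological (between-sample) variability dominates the technical
    replicate scatter.
    """
    a = rng.normal(0.0, np.sqrt(1.0 - replicate_fraction), size=(n_samples, 1))
    e = rng.normal(0.0, np.sqrt(replicate_fraction), size=(n_samples, n_reps))
    return a + e


# ---------------------------------------------------------------------------
# e-nose
# ---------------------------------------------------------------------------


@dataclass
class EnoseObservation:
    """One technical replicate: ten sensor traces plus their true plateaus."""

    stage: str
    harvest: str
    sample_id: str
    replicate: int
    traces: dict[str, SensorTrace]
    plateau: dict[str, float]


def _rise_profile(time: np.ndarray, t_plateau: float = 65.0, tau: float = 8.0) -> np.ndarray:
    """Saturating rise reaching exactly 1 at t_plateau and staying there."""
    r = (1.0 - np.exp(-time / tau)) / (1.0 - np.exp(-t_plateau / tau))
    return np.minimum(r, 1.0)


def gen_enose(
    design: StudyDesign,
    sensor_specs: Mapping[str, Mapping[str, QuantileSpec]] = SENSOR_QUANTILES,
    trace_noise_cv: float = 0.002,
) -> list[EnoseObservation]:
    """Generate e-nose traces for the full design.

    Per sample/replicate each sensor's plateau level is drawn to match the
    stage's quantile summary (see :func:`sample_from_quantiles`) with a
    sample-level random intercept nesting the technical replicates.  Traces
    are an 80 s, 1 Hz saturating rise that reaches its plateau before the
    70–75 s feature window, plus small relative sensor noise.
    """
    for s in SENSOR_NAMES:
        if s not in sensor_specs:
            raise ValueError(f"sensor_specs is missing sensor {s}")
        for stage in design.stages:
            if stage not in sensor_specs[s]:
                raise ValueError(f"sensor_specs[{s}] is missing stage {stage!r}")
    rng = np.random.default_rng(design.seed)
    time = np.arange(0.0, 81.0, 1.0)
    rise = _rise_profile(time)
    samples = list(design.iter_samples())
    n_s, n_r = len(samples), design.reps_enose
    # one nested z field per sensor so sensors vary independently
    z = {s: nested_normals(rng, n_s, n_r) for s in SENSOR_NAMES}
    noise = rng.normal(0.0, 1.0, size=(n_s, n_r, len(SENSOR_NAMES), len(time)))
    out: list[EnoseObservation] = []
    for i, (stage, harvest, sample_id) in enumerate(samples):
        for rep in range(1, n_r + 1):
            traces, plateaus = {}, {}
            for j, s in enumerate(SENSOR_NAMES):
                spec = sensor_specs[s][stage]
                p = float(sample_from_quantiles(spec, z[s][i, rep - 1]))
                value = 1.0 + (p - 1.0) * rise
                value = value * (1.0 + trace_noise_cv * noise[i, rep - 1, j])
                value = np.maximum(value, 1e-6)
                traces[s] = SensorTrace(sensor_id=s, time=time, value=value)
                plateaus[s] = p
            out.append(
                EnoseObservation(stage, harvest, sample_id, rep, traces, plateaus)
            )
    return out


# ---------------------------------------------------------------------------
# FTIR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """A Gaussian absorbance band with per-stage amplitudes."""

    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: Mapping[str, float]  # stage -> peak absorbance

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if any(a <= 0 for a in self.amplitude.values()):
            raise ValueError("band amplitudes must be positive")


#: Default band table.  The broad hydroxyl band at 3295 cm^-1 (organic
#: acids) declines with ripening; the carbonyl band at 1717 cm^-1 (esters/
#: organic acids) and the sugar fingerprint band at 1026 cm^-1 rise; the
#: CH-stretch (2928/2891) and CH2-bend (~1400) bands are stage-invariant.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band(3295.0, 160.0, {"half-red": 1.00, "red": 0.72}),
    Band(2928.0, 14.0, {"half-red": 0.22, "red": 0.22}),
    Band(2891.0, 14.0, {"half-red": 0.16, "red": 0.16}),
    Band(1717.0, 24.0, {"half-red": 0.22, "red": 0.42}),
    Band(1400.0, 30.0, {"half-red": 0.30, "red": 0.30}),
    Band(1026.0, 26.0, {"half-red": 0.55, "red": 0.95}),
)


def gen_ftir(
    design: StudyDesign,
    band_table: Sequence[Band] = DEFAULT_BANDS,
    scatter_sd: float = 0.08,
    baseline_offset_sd: float = 0.02,
    baseline_slope_sd: float = 0.006,
    amp_sample_cv: float = 0.04,
    amp_rep_cv: float = 0.013,
    noise_sd: float = 0.001,
    grid: np.ndarray = DEFAULT_GRID,
) -> SpectraSet:
    """Generate a SpectraSet for the pooled FTIR samples of the design.

    Each spectrum is a sum of Gaussian bands with stage-dependent
    amplitudes, multiplied by a per-spectrum scatter factor and offset by a
    linear baseline, plus white noise — so SNV correction is non-trivially
    exercised.  Band amplitudes carry sample-level and replicate-level
    lognormal jitter encoding the replicate nesting.
    """
    band_table = tuple(band_table)  # validates via Band
    rng = np.random.default_rng(design.seed + 1)
    grid = np.asarray(grid, float)
    shapes = np.stack(
        [np.exp(-0.5 * ((grid - b.center) / b.width) ** 2) for b in band_table]
    )
    samples = list(design.iter_ftir_samples())
    rows, stages, ids, reps = [], [], [], []
    for stage, harvest, sample_id in samples:
        amp_sample = np.exp(rng.normal(0.0, amp_sample_cv, size=len(band_table)))
        for rep in range(1, design.reps_ftir + 1):
            amp_rep = np.exp(rng.normal(0.0, amp_rep_cv, size=len(band_table)))
            amps = np.array(
                [b.amplitude[stage] for b in band_table]
            ) * amp_sample * amp_rep
            clean = amps @ shapes
            offset = rng.normal(0.04, baseline_offset_sd)
            slope = rng.normal(0.0, baseline_slope_sd)
            baseline = offset + slope * (grid - grid.mean()) / (grid[-1] - grid[0])
            scatter = np.exp(rng.normal(0.0, scatter_sd))
            spec = scatter * (clean + baseline) + rng.normal(0.0, noise_sd, len(grid))
            rows.append(spec)
            stages.append(stage)
            ids.append(sample_id)
            reps.append(rep)
    return SpectraSet(grid, np.vstack(rows), np.array(stages), np.array(ids), np.array(reps))


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

#: Synthetic 24-patch calibration palette (RGB, 8-bit).  A stand-in chart
#: spanning the gamut the way a real 24-patch reference does; values are
#: this package's own constants, not a commercial chart's.
CHECKER_PALETTE: tuple[tuple[int, int, int], ...] = (
    (115, 82, 68), (194, 150, 130), (98, 122, 157), (87, 108, 67),
    (133, 128, 177), (103, 189, 170), (214, 126, 44), (80, 91, 166),
    (193, 90, 99), (94, 60, 108), (157, 188, 64), (224, 163, 46),
    (56, 61, 150), (70, 148, 73), (175, 54, 60), (231, 199, 31),
    (187, 86, 149), (8, 133, 161), (243, 243, 242), (200, 200, 200),
    (160, 160, 160), (122, 122, 121), (85, 85, 85), (52, 52, 52),
)

#: Mean foreground colours (RGB) for ripe (red) and unripe (green) berry
#: surface, chosen so the R channel separates both regions from the dark
#: background while R-G separates red from green flesh.
RED_SURFACE_RGB = (185.0, 32.0, 40.0)
GREEN_SURFACE_RGB = (110.0, 150.0, 55.0)
BACKGROUND_RGB = (9.0, 10.0, 12.0)


@dataclass
class CheckerInfo:
    """Geometry and colours of the rendered 24-patch chart."""

    boxes: list[tuple[int, int, int, int]]  # (r0, r1, c0, c1) per patch
    reference_rgb: np.ndarray  # 24 x 3


@dataclass
class SyntheticBerryImage:
    """A rendered berry lot with exact ground-truth masks."""

    image: np.ndarray  # H x W x 3 uint8
    berry_mask: np.ndarray  # bool
    red_mask: np.ndarray  # bool, subset of berry_mask
    green_mask: np.ndarray  # bool, berry_mask minus red_mask
    berry_red_fractions: list[float]
    checker: CheckerInfo | None = None

    @property
    def true_red_pct(self) -> float:
        n = int(self.berry_mask.sum())
        return 100.0 * float(self.red_mask.sum()) / n if n else float("nan")


def render_berry_image(
    n_berries: int,
    red_fraction: float,
    rng: np.random.Generator,
    size: tuple[int, int] = (864, 1024),
    with_checker: bool = False,
    jitter: float = RED_FRACTION_JITTER,
) -> SyntheticBerryImage:
    """Render one synthetic image of a berry lot on a dark background.

    Each berry is an ellipse whose surface is split into a red-toned upper
    region and a green-toned lower region; the per-berry red fraction is
    ``red_fraction`` plus truncated Gaussian jitter, and the split is exact
    in pixel counts, so the returned masks are usable as ground truth.
    """
    if not (0.0 <= red_fraction <= 1.0):
        raise ValueError("red_fraction must lie in [0, 1]")
    h, w = size
    top_reserved = h // 5 if with_checker else 0
    # grid layout: berries must fit without overlap
    cols = int(np.ceil(np.sqrt(n_berries * w / max(h - top_reserved, 1))))
    rows_n = int(np.ceil(n_berries / cols))
    cell_h = (h - top_reserved) // rows_n
    cell_w = w // cols
    max_r = min(cell_h, cell_w) // 2 - 2
    if max_r < 4:
        raise ValueError("berries do not fit in the frame without overlap")

    img = np.empty((h, w, 3), float)
    img[:] = BACKGROUND_RGB
    img += rng.normal(0.0, 2.0, img.shape)
    berry_mask = np.zeros((h, w), bool)
    red_mask = np.zeros((h, w), bool)
    yy, xx = np.mgrid[0:h, 0:w]
    fractions: list[float] = []
    for b in range(n_berries):
        r_cell, c_cell = divmod(b, cols)
        cy = top_reserved + r_cell * cell_h + cell_h // 2
        cx = c_cell * cell_w + cell_w // 2
        ay = max_r * rng.uniform(0.82, 1.0)
        ax = max_r * rng.uniform(0.72, 0.95)
        ellipse = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        n_pix = int(ellipse.sum())
        frac = float(np.clip(red_fraction + rng.normal(0.0, jitter), 0.0, 1.0))
        if red_fraction in (0.0, 1.0):
            frac = red_fraction  # honour exact endpoint requests
        n_red = int(round(frac * n_pix))
        ys, xs = np.nonzero(ellipse)
        order = np.argsort(ys, kind="stable")  # red from the top down
        red_sel = (ys[order[:n_red]], xs[order[:n_red]])
        green_sel = (ys[order[n_red:]], xs[order[n_red:]])
        berry_mask[ellipse] = True
        red_mask[red_sel] = True
        base_red = np.array(RED_SURFACE_RGB) + rng.normal(0.0, 8.0, 3)
        base_green = np.array(GREEN_SURFACE_RGB) + rng.normal(0.0, 8.0, 3)
        img[red_sel] = base_red + rng.normal(0.0, 6.0, (n_red, 3))
        img[green_sel] = base_green + rng.normal(0.0, 6.0, (n_pix - n_red, 3))
        fractions.append(n_red / n_pix if n_pix else float("nan"))
    green_mask = berry_mask & ~red_mask

    checker = None
    if with_checker:
        pal = np.array(CHECKER_PALETTE, float)
        boxes = []
        patch_w = w // 30
        gap = patch_w // 4
        for p in range(24):
            pr, pc = divmod(p, 6)
            r0 = gap + pr * (patch_w + gap)
            c0 = gap + pc * (patch_w + gap)
            boxes.append((r0, r0 + patch_w, c0, c0 + patch_w))
            img[r0 : r0 + patch_w, c0 : c0 + patch_w] = pal[p]
        checker = CheckerInfo(boxes=boxes, reference_rgb=pal)

    return SyntheticBerryImage(
        image=np.clip(np.round(img), 0, 255).astype(np.uint8),
        berry_mask=berry_mask,
        red_mask=red_mask,
        green_mask=green_mask,
        berry_red_fractions=fractions,
        checker=checker,
    )


@dataclass
class ImageObservation:
    stage: str
    harvest: str
    sample_id: str
    replicate: int
    rendered: SyntheticBerryImage


def gen_images(
    design: StudyDesign,
    berries_per_image: int = 12,
    red_fraction: Mapping[str, float] | float | None = None,
    with_checker: bool = False,
    size: tuple[int, int] = (864, 1024),
) -> Iterator[ImageObservation]:
    """Lazily generate one image per (sample, technical replicate).

    ``red_fraction`` may be a single value, a stage -> value mapping, or
    None for the stage defaults (half-red 0.5, red 1.0).  Images are
    yielded lazily because a full design at default resolution is large.
    """
    if red_fraction is None:
        frac_by_stage = dict(STAGE_RED_FRACTION)
    elif isinstance(red_fraction, Mapping):
        frac_by_stage = dict(red_fraction)
    else:
        frac_by_stage = {s: float(red_fraction) for s in design.stages}
    for s, f in frac_by_stage.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"red_fraction for stage {s!r} outside [0, 1]")
    rng = np.random.default_rng(design.seed + 2)
    for stage, harvest, sample_id in design.iter_samples():
        for rep in range(1, design.reps_image + 1):
            rendered = render_berry_image(
                berries_per_image,
                frac_by_stage[stage],
                rng,
                size=size,
                with_checker=with_checker,
            )
            yield ImageObservation(stage, harvest, sample_id, rep, rendered)


# ---------------------------------------------------------------------------
# chemistry + VOC
# ---------------------------------------------------------------------------

#: Main VOC column names (55 generic compounds) plus the two compounds with
#: distinct, weaker stage structure: 2-methylbutanoic acid (Ac4) and
#: mesifurane (F1).  57 columns in total.
VOC_NAMES: tuple[str, ...] = tuple(f"V{i:02d}" for i in range(1, 56)) + ("Ac4", "F1")


def gen_chemistry_voc(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-sample chemistry (TA, TP, AA, TSS) and VOC (RPA%) tables.

    TA (titratable acidity, %), TP (total phenols, mg/100 g) and AA
    (antioxidant activity, %DPPH inhibition) share a positive latent factor
    and are higher in half-red fruit; TSS (°Brix) opposes that block and is
    higher in red fruit (8.8 vs 9.8 °Brix).  The 55 main VOCs load on a
    common ripening-driven aroma factor (elevated in red fruit); Ac4 and F1
    follow their own weaker latent so cluster analysis can isolate them.
    """
    rng = np.random.default_rng(design.seed + 3)
    rows = []
    voc_rows = []
    # reproducible per-compound parameters
    prng = np.random.default_rng(1_000_003)
    voc_base = prng.uniform(0.2, 3.0, size=55)
    voc_slope = prng.uniform(0.6, 1.2, size=55)
    for stage, harvest, sample_id in design.iter_samples():
        r = 1.0 if stage == "red" else 0.0
        u = rng.normal()  # shared acid/phenol latent
        ta = 0.90 - 0.20 * r + 0.06 * u + rng.normal(0.0, 0.025)
        tp = 180.0 - 25.0 * r + 12.0 * u + rng.normal(0.0, 5.0)
        aa = 75.0 - 10.0 * r + 5.0 * u + rng.normal(0.0, 2.0)
        tss = 8.8 + 1.0 * r - 0.30 * u + rng.normal(0.0, 0.20)
        rows.append(
            dict(stage=stage, harvest=harvest, sample_id=sample_id,
                 TA=ta, TP=tp, AA=aa, TSS=tss)
        )
        aroma = 1.4 * r + rng.normal(0.0, 0.30)
        side = 0.35 * r + rng.normal(0.0, 0.80)  # Ac4/F1 latent
        voc = voc_base * np.exp(voc_slope * aroma + rng.normal(0.0, 0.15, 55))
        ac4 = 0.8 * np.exp(0.5 * side + rng.normal(0.0, 0.25))
        f1 = 1.1 * np.exp(0.6 * side + rng.normal(0.0, 0.25))
        voc_rows.append(
            dict(stage=stage, harvest=harvest, sample_id=sample_id,
                 **dict(zip(VOC_NAMES[:55], voc)), Ac4=ac4, F1=f1)
        )
    chem = pd.DataFrame(rows)
    voc_df = pd.DataFrame(voc_rows, columns=["stage", "harvest", "sample_id", *VOC_NAMES])
    return chem, voc_df


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------


def write_dataset(
    design: StudyDesign,
    outdir: str | Path,
    berries_per_image: int = 12,
    image_size: tuple[int, int] = (864, 1024),
    with_checker: bool = False,
    write_images: bool = True,
) -> dict:
    """Generate and write the full synthetic dataset; returns the manifest.

    Layout: per-observation e-nose trace CSVs, a wide spectra CSV, berry
    images and ground-truth masks as PNG, chemistry/VOC/truth tables as
    CSV, and ``manifest.json`` mapping every file to its stage, harvest,
    sample and replicate.
    """
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "enose").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"design": design.__dict__ | {"stages": list(design.stages)},
                      "enose": [], "ftir": None, "images": [], "tables": {}}

    obs_list = gen_enose(design)
    truth_rows = []
    for obs in obs_list:
        fname = f"enose/trace_{obs.sample_id}_r{obs.replicate:02d}.csv"
        write_trace_csv(outdir / fname, obs.traces)
        manifest["enose"].append(
            dict(file=fname, stage=obs.stage, harvest=obs.harvest,
                 sample_id=obs.sample_id, replicate=obs.replicate)
        )
        truth_rows.append(
            dict(stage=obs.stage, harvest=obs.harvest, sample_id=obs.sample_id,
                 replicate=obs.replicate, **obs.plateau)
        )
    pd.DataFrame(truth_rows).to_csv(outdir / "enose_truth.csv", index=False)
    manifest["tables"]["enose_truth"] = "enose_truth.csv"

    spectra = gen_ftir(design)
    write_spectra_csv(outdir / "ftir_spectra.csv", spectra)
    manifest["ftir"] = "ftir_spectra.csv"

    if write_images:
        (outdir / "images").mkdir(exist_ok=True)
        img_truth = []
        for obs in gen_images(design, berries_per_image, size=image_size,
                              with_checker=with_checker):
            stem = f"images/img_{obs.sample_id}_r{obs.replicate:02d}"
            Image.fromarray(obs.rendered.image).save(outdir / f"{stem}.png")
            masks = np.stack(
                [obs.rendered.berry_mask, obs.rendered.red_mask,
                 obs.rendered.green_mask]
            ).astype(np.uint8) * 255
            Image.fromarray(np.moveaxis(masks, 0, -1)).save(outdir / f"{stem}_truth.png")
            manifest["images"].append(
                dict(file=f"{stem}.png", truth=f"{stem}_truth.png",
                     stage=obs.stage, harvest=obs.harvest,
                     sample_id=obs.sample_id, replicate=obs.replicate)
            )
            img_truth.append(
                dict(stage=obs.stage, harvest=obs.harvest, sample_id=obs.sample_id,
                     replicate=obs.replicate, true_red_pct=obs.rendered.true_red_pct)
            )
        pd.DataFrame(img_truth).to_csv(outdir / "image_truth.csv", index=False)
        manifest["tables"]["image_truth"] = "image_truth.csv"

    chem, voc = gen_chemistry_voc(design)
    chem.to_csv(outdir / "chemistry.csv", index=False)
    voc.to_csv(outdir / "voc.csv", index=False)
    manifest["tables"]["chemistry"] = "chemistry.csv"
    manifest["tables"]["voc"] = "voc.csv"

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
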