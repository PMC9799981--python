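"""Seeded synthetic data with known ground truth for every analysis arm.

Four generators emulate the statistical structure of the study's inputs:

* ``simulate_images`` — fluorescence fields with disk-shaped nuclei (DAPI)
  and diffraction-limited Gaussian spots (Cy3/Cy5) at per-cell Poisson
  rates, optionally with a configured fraction of channel-B spots placed
  next to channel-A spots (colocalization truth).
* ``simulate_lfq`` — label-free AP-MS peptide/protein intensity tables over
  a condition × compartment design with 3–4 biological and 2–3 technical
  replicates, log-normal intensities, per-run multiplicative scale offsets,
  intensity-dependent (left-censored) missingness, spiked true enrichments
  and PSM counts.
* ``simulate_ct`` — qPCR Ct tables (total and polysomal fractions, control
  and gapmer treatments) where configured per-gene recruitment effects are
  encoded so a noise-free table inverts exactly through 2^-ΔΔCT.
* ``simulate_plate`` — dual-luciferase plate readings with per-well
  multiplicative gain noise and additive background, recoverable exactly in
  the noise-free limit.

All randomness flows from the single ``seed`` in each config; equal config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spots import CY3, CY5, DAPI, ImageStack

# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


@dataclass
class SimImageConfig:
    """Synthetic smFISH field parameters.

    ``spots_per_cell_rate`` maps channel name to the Poisson mean of spots
    per nucleus.  ``coloc_fraction`` is the probability that a Cy5 spot is
    placed within ``coloc_offset`` pixels of a Cy3 spot of the same cell.
    """

    n_fields: int = 5
    image_shape: tuple[int, ...] = (256, 256)
    n_nuclei_per_field: int = 8
    nucleus_radius: float = 18.0
    spots_per_cell_rate: dict[str, float] = field(default_factory=lambda: {CY3: 2.0})
    spot_sigma: float = 1.5
    spot_amplitude: float = 100.0
    background_level: float = 10.0
    noise_sd: float = 2.0
    coloc_fraction: float = 0.0
    coloc_offset: float = 1.0
    min_spot_spacing: float = 0.0  # px, enforced within a nucleus and channel
    z_step_um: float = 0.45
    pixel_size_um: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.spots_per_cell_rate.values()):
            raise ValueError("spot rates must be non-negative")
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must be in [0, 1]")
        yx = self.image_shape[-2:]
        if self.nucleus_radius >= min(yx) / 2:
            raise ValueError("image too small to contain one nucleus")
        if len(self.image_shape) not in (2, 3):
            raise ValueError("image_shape must be 2D or 3D")

    @property
    def voxel_size(self) -> tuple[float, ...]:
        if len(self.image_shape) == 3:
            return (self.z_step_um, self.pixel_size_um, self.pixel_size_um)
        return (self.pixel_size_um, self.pixel_size_um)


def _place_nuclei(rng: np.random.Generator, config: SimImageConfig) -> np.ndarray:
    """Non-overlapping nucleus centres (y, x), rejection-sampled."""
    r = config.nucleus_radius
    ny, nx = config.image_shape[-2:]
    centres: list[tuple[float, float]] = []
    for _ in range(10_000):
        if len(centres) == config.n_nuclei_per_field:
            break
        c = (rng.uniform(r + 1, ny - r - 1), rng.uniform(r + 1, nx - r - 1))
        if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 > (2.2 * r) ** 2 for o in centres):
            centres.append(c)
    return np.array(centres)


def _render_spot(img: np.ndarray, pos: np.ndarray, amp: float, sigma: float) -> None:
    """Add an isotropic Gaussian of amplitude ``amp`` at ``pos`` in place."""
    half = int(np.ceil(4 * sigma))
    slices, grids = [], []
    for ax, p in enumerate(pos):
        lo = max(0, int(np.floor(p)) - half)
        hi = min(img.shape[ax], int(np.ceil(p)) + half + 1)
        slices.append(slice(lo, hi))
        grids.append(np.arange(lo, hi) - p)
    mesh = np.meshgrid(*grids, indexing="ij")
    d2 = sum(g**2 for g in mesh)
    img[tuple(slices)] += amp * np.exp(-d2 / (2 * sigma**2))


def simulate_images(config: SimImageConfig) -> tuple[list[ImageStack], pd.DataFrame]:
    """Simulate fields; returns (stacks, ground-truth spot table).

    Truth columns: field, channel, z, y, x, cell, coloc_with (row index of
    the Cy3 partner for colocalized Cy5 spots, −1 otherwise).  Every spot
    lies inside its nucleus; counts per cell are Poisson(rate).
    """
    rng = np.random.default_rng(config.seed)
    is3d = len(config.image_shape) == 3
    stacks: list[ImageStack] = []
    truth_rows: list[dict] = []
    channels = sorted(set(config.spots_per_cell_rate) | {CY3, CY5} - {DAPI})

    for f in range(config.n_fields):
        centres = _place_nuclei(rng, config)
        imgs = {ch: np.full(config.image_shape, config.background_level, float) for ch in channels}
        dapi = np.full(config.image_shape, config.background_level, float)
        yy, xx = np.mgrid[0 : config.image_shape[-2], 0 : config.image_shape[-1]]
        for cy, cx in centres:
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= config.nucleus_radius**2
            dapi[..., disk] += config.spot_amplitude if not is3d else config.spot_amplitude
        cell_spots: dict[int, list[int]] = {}

        for ch in channels:
            rate = config.spots_per_cell_rate.get(ch, 0.0)
            for cell, (cy, cx) in enumerate(centres, start=1):
                n = rng.poisson(rate)
                for _ in range(n):
                    # Cy5 spots may be colocalized with an existing Cy3 spot
                    partner = -1
                    if (
                        ch == CY5
                        and config.coloc_fraction > 0
                        and cell_spots.get(cell)
                        and rng.random() < config.coloc_fraction
                    ):
                        partner = int(rng.choice(cell_spots[cell]))
                        base = truth_rows[partner]
                        off = rng.normal(0, config.coloc_offset / 2, 2)
                        pos_yx = np.array([base["y"], base["x"]]) + off
                    else:
                        placed = [
                            (truth_rows[k]["y"], truth_rows[k]["x"])
                            for k in range(len(truth_rows))
                            if truth_rows[k]["field"] == f
                            and truth_rows[k]["cell"] == cell
                            and truth_rows[k]["channel"] == ch
                        ]
                        for _ in range(200):  # rejection sampling for spacing
                            rad = config.nucleus_radius * 0.8 * np.sqrt(rng.random())
                            ang = rng.uniform(0, 2 * np.pi)
                            pos_yx = np.array([cy + rad * np.sin(ang), cx + rad * np.cos(ang)])
                            if config.min_spot_spacing <= 0 or all(
                                np.hypot(pos_yx[0] - py, pos_yx[1] - px) >= config.min_spot_spacing
                                for py, px in placed
                            ):
                                break
                    if is3d:
                        z = rng.uniform(1, config.image_shape[0] - 2)
                        pos = np.array([z, *pos_yx])
                    else:
                        pos = pos_yx
                    _render_spot(imgs[ch], pos, config.spot_amplitude, config.spot_sigma)
                    row = {
                        "field": f,
                        "channel": ch,
                        "z": float(pos[0]) if is3d else 0.0,
                        "y": float(pos_yx[0]),
                        "x": float(pos_yx[1]),
                        "cell": cell,
                        "coloc_with": partner,
                    }
                    if ch == CY3:
                        cell_spots.setdefault(cell, []).append(len(truth_rows))
                    truth_rows.append(row)

        if config.noise_sd > 0:
            dapi = dapi + rng.normal(0, config.noise_sd, dapi.shape)
            for ch in channels:
                imgs[ch] = imgs[ch] + rng.normal(0, config.noise_sd, imgs[ch].shape)
        all_ch = {DAPI: np.clip(dapi, 0, None)}
        all_ch.update({ch: np.clip(imgs[ch], 0, None) for ch in channels})
        stacks.append(ImageStack(all_ch, voxel_size=config.voxel_size))

    truth = pd.DataFrame(
        truth_rows, columns=["field", "channel", "z", "y", "x", "cell", "coloc_with"]
    )
    return stacks, truth


# ---------------------------------------------------------------------------
# label-free MS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissingModel:
    """Logistic, intensity-dependent missingness: the probability that a
    measurement is censored decreases with its log2 intensity.

    P(missing | x) = max_rate / (1 + exp((x − midpoint) / scale))
    """

    midpoint: float = 18.0
    scale: float = 1.0
    max_rate: float = 0.9

    def prob(self, log2_intensity: np.ndarray) -> np.ndarray:
        return self.max_rate / (1.0 + np.exp((log2_intensity - self.midpoint) / self.scale))


@dataclass(frozen=True)
class Spike:
    """A true enrichment: ``protein`` shifted by ``log2fc`` in group1 of the
    named canonical comparison."""

    protein: str
    comparison: str
    log2fc: float


@dataclass
class SimLfqConfig:
    """Synthetic AP-MS design: (condition × compartment) groups, 3–4
    biological × 2–3 technical replicates, log-normal intensities with
    per-run scale offsets, left-censored missingness, spiked enrichments."""

    n_proteins: int = 500
    conditions: tuple[str, ...] = ("normoxia", "hypoxia")
    compartments: tuple[str, ...] = ("nucleus", "cytoplasm")
    n_bio_replicates: int = 3
    n_tech_replicates: int = 2
    log_intensity_mean: float = 22.0
    log_intensity_sd: float = 2.5
    bio_sd: float = 0.3
    tech_sd: float = 0.1
    run_scale_sd: float = 0.2
    missing_model: MissingModel | None = field(default_factory=MissingModel)
    spiked: tuple[Spike, ...] = ()
    psm_rate: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio_replicates < 2:
            raise ValueError("need at least 2 biological replicates")
        seen = set()
        for s in self.spiked:
            if not np.isfinite(s.log2fc):
                raise ValueError("spiked log2FC must be finite")
            key = (s.protein, s.comparison)
            if key in seen:
                raise ValueError(f"overlapping spike definitions for {key}")
            seen.add(key)

    @property
    def groups(self) -> list[tuple[str, str]]:
        return list(itertools.product(self.conditions, self.compartments))


@dataclass
class SimLfq:
    """Output bundle of :func:`simulate_lfq`."""

    peptides: pd.DataFrame  # peptide-level intensities (wide) with 'protein', 'peptide'
    proteins: pd.DataFrame  # protein × run intensities with missing entries (NaN)
    psm: pd.DataFrame  # protein × run PSM counts
    annotation: pd.DataFrame  # run -> condition, compartment, bio_rep, tech_rep
    truth: pd.DataFrame  # protein, comparison, true_log2fc (spiked rows only)


def simulate_lfq(config: SimLfqConfig) -> SimLfq:
    """Simulate a label-free AP-MS dataset with known enrichment truth.

    Spiked proteins are shifted by their stated log2FC in group1 of the
    stated comparison only; missingness frequency is monotone non-increasing
    in true intensity (left censoring).
    """
    from .enrichment import CANONICAL_COMPARISONS

    comparisons = {c.name: c for c in CANONICAL_COMPARISONS}
    for s in config.spiked:
        if s.comparison not in comparisons:
            raise ValueError(f"unknown comparison {s.comparison!r}")

    rng = np.random.default_rng(config.seed)
    prot_ids = [f"P{i:05d}" for i in range(config.n_proteins)]
    base = rng.normal(config.log_intensity_mean, config.log_intensity_sd, config.n_proteins)

    # group-level true means (log2), keyed "condition|compartment"
    group_mean = pd.DataFrame(
        {f"{c}|{k}": base.copy() for c, k in config.groups}, index=prot_ids, dtype=float
    )
    for s in config.spiked:
        cond, comp = comparisons[s.comparison].group1
        group_mean.loc[s.protein, f"{cond}|{comp}"] += s.log2fc

    runs, ann_rows = [], []
    values = {}
    for cond, comp in config.groups:
        for b in range(1, config.n_bio_replicates + 1):
            bio_noise = rng.normal(0, config.bio_sd, config.n_proteins)
            for t in range(1, config.n_tech_replicates + 1):
                run = f"{cond}_{comp}_b{b}_t{t}"
                run_offset = rng.normal(0, config.run_scale_sd)
                tech_noise = rng.normal(0, config.tech_sd, config.n_proteins)
                values[run] = (
                    group_mean[f"{cond}|{comp}"].to_numpy() + bio_noise + tech_noise + run_offset
                )
                runs.append(run)
                ann_rows.append(
                    {
                        "run": run,
                        "condition": cond,
                        "compartment": comp,
                        "bio_rep": f"{cond}_{comp}_b{b}",
                        "tech_rep": t,
                    }
                )
    log2_int = pd.DataFrame(values, index=prot_ids)
    annotation = pd.DataFrame(ann_rows).set_index("run")

    proteins = (2.0**log2_int).copy()
    if config.missing_model is not None:
        p_miss = config.missing_model.prob(log2_int.to_numpy())
        mask = rng.random(p_miss.shape) < p_miss
        proteins = proteins.mask(mask)

    # two peptides per protein splitting its intensity; peptide-level table
    frac = rng.beta(4, 4, config.n_proteins)
    pep_rows = []
    for i, pid in enumerate(prot_ids):
        for j, fr in enumerate((frac[i], 1 - frac[i])):
            pep_rows.append({"peptide": f"{pid}_pep{j}", "protein": pid, **(proteins.iloc[i] * fr)})
    peptides = pd.DataFrame(pep_rows)

    lam = config.psm_rate * 2.0 ** ((log2_int.to_numpy() - config.log_intensity_mean) / 4.0)
    psm = pd.DataFrame(rng.poisson(np.clip(lam, 0, 1e6)), index=prot_ids, columns=runs)
    psm = psm.mask(proteins.isna(), 0)

    truth = pd.DataFrame(
        [
            {"protein": s.protein, "comparison": s.comparison, "true_log2fc": s.log2fc}
            for s in config.spiked
            if s.log2fc != 0
        ],
        columns=["protein", "comparison", "true_log2fc"],
    )
    return SimLfq(peptides, proteins, psm, annotation, truth)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass
class SimCtConfig:
    """Synthetic Fluidigm-style Ct table over fractions × treatments.

    ``true_recruitment_log2fc`` maps (gene, treatment) to the configured
    polysome-recruitment effect (log2), applied to the polysomal fraction
    only; the reference gene always has effect 0.
    """

    genes: dict[str, str] = field(
        default_factory=lambda: {"Fgf1": "IRES", "Vegfa": "IRES", "Nono": "ITAF", "Actb": "other"}
    )
    reference_gene: str = "Gapdh"
    treatments: tuple[str, ...] = ("control", "gapmer_Neat1", "gapmer_Neat1_2")
    fractions: tuple[str, ...] = ("total", "polysomal")
    true_recruitment_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    ct_noise_sd: float = 0.0
    n_bio_replicates: int = 2
    n_tech_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must not be empty")
        for (gene, treatment), fc in self.true_recruitment_log2fc.items():
            if gene == self.reference_gene:
                if fc != 0:
                    raise ValueError("reference gene must have zero effect")
            elif gene not in self.genes:
                raise ValueError(f"effect configured for unknown gene {gene!r}")
            if treatment not in self.treatments:
                raise ValueError(f"effect configured for unknown treatment {treatment!r}")


def simulate_ct(config: SimCtConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format Ct table plus per-gene truth.

    A recruitment effect of +1 log2 lowers the treatment's polysomal Ct by
    one cycle relative to the calibrator (first treatment), so ΔΔCT on a
    noise-free table recovers the configured effect exactly.  Per-sample
    additive offsets emulate plate-level shifts (they cancel in ΔCt).
    Ct values are clipped to [5, 40].
    """
    rng = np.random.default_rng(config.seed)
    gene_base = {g: rng.uniform(22, 30) for g in config.genes}
    gene_base[config.reference_gene] = rng.uniform(18, 20)
    all_genes = dict(config.genes)
    all_genes.setdefault(config.reference_gene, "other")

    rows = []
    for frac in config.fractions:
        for treat in config.treatments:
            for b in range(1, config.n_bio_replicates + 1):
                sample_offset = rng.normal(0, 0.5)
                for g, cls in all_genes.items():
                    effect = 0.0
                    if frac == "polysomal" and g != config.reference_gene:
                        effect = config.true_recruitment_log2fc.get((g, treat), 0.0)
                    true_ct = gene_base[g] + sample_offset - effect
                    for t in range(1, config.n_tech_replicates + 1):
                        ct = true_ct + (
                            rng.normal(0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0
                        )
                        rows.append(
                            {
                                "gene": g,
                                "gene_class": cls,
                                "fraction": frac,
                                "treatment": treat,
                                "bio_rep": b,
                                "tech_rep": t,
                                "ct": float(np.clip(ct, 5, 40)),
                            }
                        )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {
                "gene": g,
                "treatment": tr,
                "true_log2fc": config.true_recruitment_log2fc.get((g, tr), 0.0),
            }
            for g in config.genes
            for tr in config.treatments
        ]
    )
    return table, truth


# ---------------------------------------------------------------------------
# luciferase plates
# ---------------------------------------------------------------------------


@dataclass
class SimPlateConfig:
    """Synthetic dual-luciferase plate: per-construct/condition true
    LucF/LucR ratios, per-well multiplicative gain noise (CV) and additive
    background, plus non-transduced background wells."""

    constructs: tuple[str, ...] = ("FGF1", "hairpin")
    conditions: tuple[str, ...] = ("normoxia", "hypoxia")
    true_ires_activity: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("FGF1", "normoxia"): 0.2,
            ("FGF1", "hypoxia"): 0.4,
            ("hairpin", "normoxia"): 0.004,
            ("hairpin", "hypoxia"): 0.004,
        }
    )
    lucR_scale: float = 10_000.0
    gain_cv: float = 0.1
    background_mean: float = 500.0
    background_sd: float = 0.0
    n_bio: int = 9
    n_tech: int = 3
    n_background_wells: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lucR_scale <= 0:
            raise ValueError("lucR_scale must be positive")
        for key, v in self.true_ires_activity.items():
            if v <= 0:
                raise ValueError(f"true ratio for {key} must be positive")
        missing = [
            (c, k)
            for c in self.constructs
            for k in self.conditions
            if (c, k) not in self.true_ires_activity
        ]
        if missing:
            raise ValueError(f"true_ires_activity missing for {missing}")


def simulate_plate(config: SimPlateConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate plate readings plus the configured truth table.

    Each well: LucR = lucR_scale · bio_gain · gR + background and
    LucF = true_ratio · lucR_scale · bio_gain · gF + background, where
    ``bio_gain`` is a per-biological-replicate log-normal scale (shared by
    both channels, e.g. cell number) and gR, gF are independent per-channel
    measurement gains with CV ``gain_cv``.  With gain_cv = background_sd = 0
    background-subtracted ratios equal the configured truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.gain_cv**2))

    def _gain() -> float:
        return float(np.exp(rng.normal(-sigma**2 / 2, sigma))) if sigma else 1.0

    rows = []
    well = 0
    for cond in config.conditions:
        for construct in config.constructs:
            ratio = config.true_ires_activity[(construct, cond)]
            for b in range(1, config.n_bio + 1):
                bio_gain = _gain()
                for t in range(1, config.n_tech + 1):
                    bg = (
                        rng.normal(config.background_mean, config.background_sd)
                        if config.background_sd
                        else config.background_mean
                    )
                    rows.append(
                        {
                            "well": f"W{well:04d}",
                            "construct": construct,
                            "condition": cond,
                            "bio_rep": b,
                            "tech_rep": t,
                            "lucR": config.lucR_scale * bio_gain * _gain() + bg,
                            "lucF": ratio * config.lucR_scale * bio_gain * _gain() + bg,
                            "is_background": False,
                        }
                    )
                    well += 1
    for _ in range(config.n_background_wells):
        bgR = (
            rng.normal(config.background_mean, config.background_sd)
            if config.background_sd
            else config.background_mean
        )
        bgF = (
            rng.normal(config.background_mean, config.background_sd)
            if config.background_sd
            else config.background_mean
        )
        rows.append(
            {
                "well": f"W{well:04d}",
                "construct": "",
                "condition": "",
                "bio_rep": 0,
                "tech_rep": 0,
                "lucR": max(bgR, 0.0),
                "lucF": max(bgF, 0.0),
                "is_background": True,
            }
        )
        well += 1
    readings = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {"construct": c, "condition": k, "true_ratio": v}
            for (c, k), v in config.true_ires_activity.items()
        ]
    )
    return readings, truth
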