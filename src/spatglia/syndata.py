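"""Seeded synthetic spot-level datasets with the structure the pipeline assumes.

The generator emulates a Visium-style study of an amyloid-pathology mouse
model: eight coronal-section samples (2 genotypes x 2 ages x 2
replicates), spots on an offset hex-like lattice, anatomical regions
(cortex layers, hippocampus, striatum, thalamus, a white-matter band,
border/meninges), negative-binomial counts driven by per-region expression
programs, and disease-associated microglia/astrocyte (DAM/DAA) activation
programs whose spatial extent depends on genotype and age: activation
appears in white matter at 3 months in the AD genotype and spreads to gray
matter by 7 months, while border regions carry a constant BAM-like
baseline in every animal.

Counts follow ``mean(gene, spot) = baseline * fold ** activation`` with a
mean/size negative-binomial parameterization (variance = m + m^2/size).
All outputs are bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .io import SpotDataset, merge_samples
from .transforms import Transform, TransformChain, identity_chain

REGIONS = ("cortex_outer", "cortex_inner", "hippocampus", "striatum",
           "thalamus", "WM", "border")
GM_REGIONS = ("cortex_outer", "cortex_inner", "hippocampus", "striatum",
              "thalamus")

DAM_GENES = ["Lpl", "Cst7", "Axl", "Itgax", "Spp1", "Cd9", "Ccl6", "Csf1"]
DAA_GENES = ["Ggta1", "Gsn", "Osmr", "Vim", "Serpina3n", "Ctsb", "Gfap"]
MICROGLIAL_PANEL = [
    "Hexb", "Cst3", "Cx3cr1", "Ctsd", "Csf1r", "Ctss", "Sparc", "Tmsb4x",
    "P2ry12", "C1qa", "C1qb", "Tmem119", "Tyrobp", "Ctsb", "Apoe", "B2m",
    "Fth1", "Lyz2", "Trem2", "Axl", "Cst7", "Ctsl", "Lpl", "Cd9", "Csf1",
    "Ccl6", "Itgax", "Timp2",
]
# Panel genes that rise with activation but are not part of the printed DAM
# score set, and the homeostatic genes that fall as microglia activate.
DAM_AUX_GENES = ["Apoe", "B2m", "Fth1", "Lyz2", "Trem2", "Ctsl", "Timp2"]
HOMEOSTATIC_GENES = ["Hexb", "Cst3", "Cx3cr1", "Ctsd", "Csf1r", "Ctss",
                     "Sparc", "Tmsb4x", "P2ry12", "C1qa", "C1qb", "Tmem119",
                     "Tyrobp"]

STUDY_SAMPLES = [
    ("WT", "3M", "rep1"), ("WT", "3M", "rep2"),
    ("WT", "7M", "rep1"), ("WT", "7M", "rep2"),
    ("AD", "3M", "rep1"), ("AD", "3M", "rep2"),
    ("AD", "7M", "rep1"), ("AD", "7M", "rep2"),
]


# ---------------------------------------------------------------------------
# tissue geometry


@dataclass
class Band:
    """Horizontal band of grid rows ``[row_lo, row_hi)``."""

    label: str
    row_lo: int
    row_hi: int

    def paint(self, region_map: np.ndarray) -> None:
        region_map[self.row_lo:self.row_hi, :] = self.label


@dataclass
class Blob:
    """Elliptical blob painted over whatever lies beneath it."""

    label: str
    center_row: float
    center_col: float
    r_row: float
    r_col: float

    def paint(self, region_map: np.ndarray) -> None:
        rr, cc = np.mgrid[0:region_map.shape[0], 0:region_map.shape[1]]
        inside = (((rr - self.center_row) / self.r_row) ** 2
                  + ((cc - self.center_col) / self.r_col) ** 2) <= 1.0
        region_map[inside] = self.label


@dataclass
class TissueDesign:
    """Grid layout plus parametric region geometry (bands, then blobs)."""

    n_rows: int
    n_cols: int
    spot_spacing: float = 5.0
    geometry: list = field(default_factory=list)

    def region_map(self) -> np.ndarray:
        grid = np.full((self.n_rows, self.n_cols), "", dtype=object)
        for shape in self.geometry:
            shape.paint(grid)
        return grid

    def region_labels(self):
        return sorted({shape.label for shape in self.geometry})


def default_design(n_rows: int = 40, n_cols: int = 50,
                   spot_spacing: float = 5.0) -> TissueDesign:
    """Coronal-section analog: stacked bands with a hippocampal blob.

    Region boundaries scale with ``n_rows`` so scaled-down designs keep
    every region non-empty (``n_rows >= 14`` recommended).
    """
    n = n_rows
    wm_lo, wm_hi = int(0.36 * n), max(int(0.44 * n), int(0.36 * n) + 2)
    geometry = [
        Band("border", 0, 1),
        Band("cortex_outer", 1, int(0.20 * n)),
        Band("cortex_inner", int(0.20 * n), wm_lo),
        Band("WM", wm_lo, wm_hi),
        Band("striatum", wm_hi, int(0.75 * n)),
        Band("thalamus", int(0.75 * n), n - 1),
        Band("border", n - 1, n),
        Blob("hippocampus", center_row=0.58 * n, center_col=0.30 * n_cols,
             r_row=0.11 * n, r_col=0.22 * n_cols),
    ]
    return TissueDesign(n_rows, n_cols, spot_spacing, geometry)


def build_tissue(design: TissueDesign) -> pd.DataFrame:
    """Lay out spots on an offset (hex-like) lattice with region labels.

    Returns a table with ``spot_id, array_row, array_col, x_px, y_px,
    region``; odd rows are shifted by half a spacing in x, and row pitch is
    ``spacing * sqrt(3)/2``, mirroring Visium hex packing.
    """
    if design.n_rows < 2 or design.n_cols < 2:
        raise ValueError("tissue grid needs n_rows, n_cols >= 2")
    grid = design.region_map()
    if (grid == "").any():
        raise ValueError("region geometry leaves unlabeled grid positions")
    for label in design.region_labels():
        if not (grid == label).any():
            raise ValueError(f"region {label!r} has zero spots")
    rows, cols = np.mgrid[0:design.n_rows, 0:design.n_cols]
    rows, cols = rows.ravel(), cols.ravel()
    x = (cols + 0.5 * (rows % 2)) * design.spot_spacing
    y = rows * design.spot_spacing * np.sqrt(3) / 2
    return pd.DataFrame({
        "spot_id": [f"spot_{r:03d}x{c:03d}" for r, c in zip(rows, cols)],
        "array_row": rows,
        "array_col": cols,
        "x_px": x,
        "y_px": y,
        "region": grid[rows, cols],
    })


# ---------------------------------------------------------------------------
# expression programs and activation fields


@dataclass
class GeneProgram:
    """A set of genes sharing a baseline, activation fold, and dispersion.

    Mean expression of a member gene in a spot with activation ``a`` is
    ``baseline_mean * fold ** a``; ``fold > 1`` spikes up with activation,
    ``fold < 1`` is depleted, ``fold == 1`` is activation-independent.
    """

    name: str
    genes: list
    baseline_mean: np.ndarray
    fold: float = 1.0
    dispersion: float = 8.0

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"program {self.name!r} has no genes")
        if not self.fold > 0:
            raise ValueError(f"program {self.name!r}: fold must be > 0")
        if not self.dispersion > 0:
            raise ValueError(f"program {self.name!r}: dispersion must be > 0")
        self.baseline_mean = np.broadcast_to(
            np.asarray(self.baseline_mean, dtype=float), (len(self.genes),)
        ).copy()


@dataclass
class ActivationField:
    """Per-program activation level as a function of (genotype, age, region).

    ``levels[program][(genotype, age)][region]`` gives the activation in
    [0, 1]; missing entries default to 0.  Programs absent from ``levels``
    are activation-0 everywhere (their fold is never applied).
    """

    levels: dict = field(default_factory=dict)

    def activation(self, program: str, genotype: str, age: str,
                   region: str) -> float:
        by_group = self.levels.get(program, {})
        by_region = by_group.get((genotype, age), {})
        value = by_region.get(region, by_region.get("*", 0.0))
        if not 0.0 <= value <= 1.0:
            raise ValueError(
                f"activation {value} for {program}/{genotype}-{age}/{region} "
                f"outside [0, 1]")
        return value

    def spot_levels(self, program: str, genotype: str, age: str,
                    regions: np.ndarray) -> np.ndarray:
        return np.array([self.activation(program, genotype, age, r)
                         for r in regions])


def default_activation_field(*, wm_3m: float = 0.8, gm_3m: float = 0.1,
                             wm_7m: float = 1.0, gm_7m: float = 0.8,
                             border_level: float = 0.4) -> ActivationField:
    """Encodes the WM-early / GM-late activation pattern.

    AD animals activate the white matter strongly at 3 months with only a
    whisper in gray matter; by 7 months activation saturates in WM and has
    spread through GM.  WT animals are 0 everywhere except the BAM-like
    border baseline shared by all genotypes.  Region-identity programs are
    fully on in their own region for every animal.
    """
    def disease(wm, gm):
        table = {r: gm for r in GM_REGIONS}
        table["WM"] = wm
        table["border"] = border_level
        return table

    border_only = {"border": border_level}
    glial = {
        ("AD", "3M"): disease(wm_3m, gm_3m),
        ("AD", "7M"): disease(wm_7m, gm_7m),
        ("WT", "3M"): dict(border_only),
        ("WT", "7M"): dict(border_only),
    }
    levels = {name: {k: dict(v) for k, v in glial.items()}
              for name in ("DAM", "DAA", "DAM_aux", "microglia_homeostatic")}
    for region in REGIONS:
        levels[f"region_{region}"] = {
            (g, a): {region: 1.0}
            for g in ("WT", "AD") for a in ("3M", "7M")
        }
    return ActivationField(levels)


def default_programs(n_genes: int = 2500, *, dam_fold: float = 2.0,
                     daa_fold: float = 2.0, region_fold: float = 3.0,
                     n_region_markers: int = 60, dispersion: float = 8.0,
                     baseline_seed: int = 7) -> list:
    """Default gene universe: printed glial gene sets + region markers +
    lognormal background, totalling ``n_genes`` genes."""
    rng = np.random.default_rng(baseline_seed)
    programs = [
        GeneProgram("DAM", list(DAM_GENES), 2.0, dam_fold, dispersion),
        GeneProgram("DAM_aux", list(DAM_AUX_GENES), 2.0, dam_fold, dispersion),
        GeneProgram("microglia_homeostatic", list(HOMEOSTATIC_GENES), 2.0,
                    0.7, dispersion),
        GeneProgram("DAA", list(DAA_GENES), 2.0, daa_fold, dispersion),
    ]
    for region in REGIONS:
        genes = [f"{region}_mk{j:02d}" for j in range(n_region_markers)]
        programs.append(GeneProgram(f"region_{region}", genes, 0.8,
                                    region_fold, dispersion))
    n_named = sum(len(p.genes) for p in programs)
    if n_genes < n_named + 1:
        raise ValueError(f"n_genes must exceed {n_named} named genes")
    n_bg = n_genes - n_named
    baselines = rng.lognormal(mean=-0.7, sigma=1.0, size=n_bg)
    programs.append(GeneProgram(
        "background", [f"gene_{i:04d}" for i in range(n_bg)], baselines,
        1.0, dispersion))
    return programs


# ---------------------------------------------------------------------------
# count simulation


@dataclass
class SyntheticDataset:
    """A simulated sample (or merged study) plus its ground truth."""

    data: SpotDataset
    activation: pd.DataFrame  # spots x programs, in [0, 1]
    programs: list
    seed: int
    image: np.ndarray | None = None
    image_truth: "PlaqueImage | None" = None

    @property
    def regions(self) -> np.ndarray:
        return self.data.meta["region"].to_numpy()


def _program_table(programs) -> tuple:
    genes, baseline, fold, size, prog_of_gene = [], [], [], [], []
    for p in programs:
        genes.extend(p.genes)
        baseline.append(p.baseline_mean)
        fold.extend([p.fold] * len(p.genes))
        size.extend([p.dispersion] * len(p.genes))
        prog_of_gene.extend([p.name] * len(p.genes))
    gene_ids = np.asarray(genes, dtype=object)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("programs assign some gene more than once")
    return (gene_ids, np.concatenate(baseline), np.asarray(fold),
            np.asarray(size), np.asarray(prog_of_gene, dtype=object))


def simulate_counts(spot_table: pd.DataFrame, programs: list,
                    activationfield: ActivationField | None = None, *,
                    genotype: str = "WT", age: str = "3M",
                    sample: str = "sample", lib_size_mean: float | None = None,
                    activation_override: dict | None = None,
                    seed: int = 0) -> SyntheticDataset:
    """Draw negative-binomial counts for one sample.

    Expected counts are ``baseline * fold ** activation`` per gene/spot;
    when ``lib_size_mean`` is given, each spot's mean vector is rescaled so
    its expected total equals ``lib_size_mean``.  ``activation_override``
    maps program names to per-spot activation arrays in [0, 1] and takes
    precedence over the rule-based field (used for gradient simulations).
    """
    if lib_size_mean is not None and not lib_size_mean > 0:
        raise ValueError("lib_size_mean must be > 0")
    gene_ids, baseline, fold, size, prog_of_gene = _program_table(programs)
    n_spots = len(spot_table)
    if n_spots == 0:
        raise ValueError("spot table is empty")
    regions = spot_table["region"].to_numpy()

    act = pd.DataFrame(0.0, index=spot_table["spot_id"],
                       columns=[p.name for p in programs])
    for p in programs:
        if activation_override and p.name in activation_override:
            levels = np.asarray(activation_override[p.name], dtype=float)
            if levels.shape != (n_spots,):
                raise ValueError(
                    f"override for {p.name!r} must have one value per spot")
            if levels.min() < 0 or levels.max() > 1:
                raise ValueError(f"override for {p.name!r} outside [0, 1]")
        elif activationfield is not None:
            levels = activationfield.spot_levels(p.name, genotype, age, regions)
        else:
            levels = np.zeros(n_spots)
        act[p.name] = levels

    mean = np.empty((len(gene_ids), n_spots), dtype=float)
    row = 0
    for p in programs:
        k = len(p.genes)
        a = act[p.name].to_numpy()[None, :]
        mean[row:row + k] = (baseline[row:row + k, None]
                             * np.power(p.fold, a))
        row += k
    if not np.all(np.isfinite(mean)):
        raise ValueError("non-finite expected counts; check folds/baselines")
    if lib_size_mean is not None:
        totals = mean.sum(axis=0)
        mean *= lib_size_mean / totals[None, :]

    rng = np.random.default_rng(seed)
    nb_p = size[:, None] / (size[:, None] + mean)
    counts = rng.negative_binomial(size[:, None], nb_p)

    positions = pd.DataFrame({
        "array_row": spot_table["array_row"].to_numpy(),
        "array_col": spot_table["array_col"].to_numpy(),
        "x_px": spot_table["x_px"].to_numpy(),
        "y_px": spot_table["y_px"].to_numpy(),
    }, index=pd.Index(spot_table["spot_id"], name="barcode"))
    meta = pd.DataFrame({
        "sample": sample, "genotype": genotype, "age": age,
        "region": regions,
    }, index=positions.index)
    data = SpotDataset(sp.csr_matrix(counts), gene_ids,
                       spot_table["spot_id"].to_numpy(dtype=object),
                       positions, meta)
    return SyntheticDataset(data, act, programs, seed)


def expected_mean(programs: list, activation: dict) -> pd.Series:
    """Closed-form expected count per gene for given program activations."""
    gene_ids, baseline, fold, _, prog = _program_table(programs)
    a = np.array([activation.get(p, 0.0) for p in prog])
    return pd.Series(baseline * np.power(fold, a), index=gene_ids)


def simulate_study(seed: int = 0, *, n_rows: int = 40, n_cols: int = 50,
                   n_genes: int = 2500, dam_fold: float = 2.0,
                   daa_fold: float = 2.0, region_fold: float = 3.0,
                   n_region_markers: int = 60, gm_3m: float = 0.1,
                   samples=None,
                   lib_size_mean: float | None = None) -> SyntheticDataset:
    """Simulate the full 2 genotypes x 2 ages x 2 replicates study.

    Returns a merged dataset (default 8 samples x 2,000 spots, 2,500
    genes) whose meta carries sample, genotype, age and ground-truth
    region, and whose ``activation`` table holds per-spot truth levels.
    """
    design = default_design(n_rows, n_cols)
    tissue = build_tissue(design)
    programs = default_programs(n_genes, dam_fold=dam_fold, daa_fold=daa_fold,
                                region_fold=region_fold,
                                n_region_markers=n_region_markers)
    act_field = default_activation_field(gm_3m=gm_3m)
    samples = STUDY_SAMPLES if samples is None else samples
    child = np.random.SeedSequence(seed).generate_state(len(samples))
    parts, acts = [], []
    for (genotype, age, rep), s in zip(samples, child):
        name = f"{genotype}-{age}-{rep}"
        sd = simulate_counts(tissue, programs, act_field, genotype=genotype,
                             age=age, sample=name,
                             lib_size_mean=lib_size_mean, seed=int(s))
        parts.append(sd.data)
        a = sd.activation.copy()
        a.index = [f"{name}_{i}" for i in a.index]
        acts.append(a)
    merged = merge_samples(parts)
    return SyntheticDataset(merged, pd.concat(acts), programs, seed)


def two_group_dataset(n_spots_per_group: int = 200, n_genes: int = 1000, *,
                      spike_genes=None, fold: float = 2.0,
                      dispersion: float = 8.0, baseline: float = 4.0,
                      seed: int = 0) -> SyntheticDataset:
    """Flat two-group design: spike genes at activation 1 in group AD.

    Used for differential-expression calibration/power and module-score
    checks; spots sit on a plain lattice with no region structure beyond a
    single 'GM' label.
    """
    spike_genes = list(DAM_GENES) if spike_genes is None else list(spike_genes)
    rng = np.random.default_rng(seed)
    n_bg = n_genes - len(spike_genes)
    if n_bg < 1:
        raise ValueError("n_genes must exceed the number of spike genes")
    programs = [
        GeneProgram("spike", spike_genes, baseline, fold, dispersion),
        GeneProgram("background", [f"gene_{i:04d}" for i in range(n_bg)],
                    rng.lognormal(-0.7, 1.0, n_bg), 1.0, dispersion),
    ]
    n = 2 * n_spots_per_group
    n_cols = int(np.ceil(np.sqrt(n)))
    rows = np.arange(n) // n_cols
    cols = np.arange(n) % n_cols
    table = pd.DataFrame({
        "spot_id": [f"s{i:05d}" for i in range(n)],
        "array_row": rows, "array_col": cols,
        "x_px": (cols + 0.5 * (rows % 2)) * 5.0,
        "y_px": rows * 5.0 * np.sqrt(3) / 2,
        "region": "GM",
    })
    activation = np.zeros(n)
    activation[:n_spots_per_group] = 1.0
    sdata = simulate_counts(table, programs,
                            activation_override={"spike": activation},
                            seed=seed + 1)
    sdata.data.meta["genotype"] = np.where(activation > 0, "AD", "WT")
    sdata.data.meta["group"] = sdata.data.meta["genotype"]
    return sdata


def gradient_dataset(n_spots: int = 500, n_genes: int = 300, *,
                     fold: float = 8.0, dispersion: float = 8.0,
                     late_prob_scale: float = 0.85,
                     seed: int = 0) -> SyntheticDataset:
    """Continuous activation gradient for trajectory recovery.

    Each spot gets a latent activation ``u ~ Uniform(0, 1)``; activated
    panel genes follow ``fold ** u``, homeostatic panel genes ``fold **
    -u``.  Group labels emulate the study design: a spot is labeled
    (AD, 7M) with probability ``late_prob_scale * u`` (the late pole), and
    otherwise drawn from the remaining genotype/age combinations, so the
    low-activation pole is WT-dominated.  The truth gradient is stored in
    the activation table column ``"activated"``.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 1, n_spots)
    activated = [g for g in MICROGLIAL_PANEL if g not in HOMEOSTATIC_GENES]
    n_bg = n_genes - len(MICROGLIAL_PANEL)
    if n_bg < 1:
        raise ValueError("n_genes must exceed the 28-gene panel")
    programs = [
        GeneProgram("activated", activated, 1.5, fold, dispersion),
        GeneProgram("homeostatic", list(HOMEOSTATIC_GENES), 1.5 * fold,
                    1.0 / fold, dispersion),
        GeneProgram("background", [f"gene_{i:04d}" for i in range(n_bg)],
                    rng.lognormal(-0.7, 1.0, n_bg), 1.0, dispersion),
    ]
    n_cols = int(np.ceil(np.sqrt(n_spots)))
    rows = np.arange(n_spots) // n_cols
    cols = np.arange(n_spots) % n_cols
    table = pd.DataFrame({
        "spot_id": [f"s{i:05d}" for i in range(n_spots)],
        "array_row": rows, "array_col": cols,
        "x_px": (cols + 0.5 * (rows % 2)) * 5.0,
        "y_px": rows * 5.0 * np.sqrt(3) / 2,
        "region": "GM",
    })
    sdata = simulate_counts(table, programs,
                            activation_override={"activated": u,
                                                 "homeostatic": u},
                            seed=seed + 1)
    late = rng.uniform(0, 1, n_spots) < late_prob_scale * u
    others = [("WT", "3M"), ("WT", "7M"), ("AD", "3M")]
    picks = rng.integers(0, len(others), n_spots)
    genotype = np.where(late, "AD", [others[i][0] for i in picks])
    age = np.where(late, "7M", [others[i][1] for i in picks])
    sdata.data.meta["genotype"] = genotype
    sdata.data.meta["age"] = age
    return sdata


def plaque_dataset(n_genes: int = 500, *, driver_gene: str = "Cst7",
                   driver_fold: float = 6.0, n_blobs: int = 6,
                   blob_sigma_px: float = 14.0, n_rows: int = 40,
                   n_cols: int = 50, seed: int = 0) -> SyntheticDataset:
    """Single AD-7M sample whose driver gene follows focal plaque blobs.

    Amyloid deposits are focal: the driver gene's activation is a smooth
    field of Gaussian bumps (normalized to [0, 1]) dropped at random
    tissue positions, while the remaining DAM/DAA/region programs follow
    the usual rule-based field.  The blob field is stored in the
    activation table column ``"plaque"`` and is the ground truth for
    image-latent association checks.
    """
    rng = np.random.default_rng(seed)
    design = default_design(n_rows, n_cols)
    tissue = build_tissue(design)
    programs = default_programs(n_genes)
    for p in programs:
        if driver_gene in p.genes:
            keep = [g != driver_gene for g in p.genes]
            p.genes = [g for g in p.genes if g != driver_gene]
            p.baseline_mean = p.baseline_mean[np.asarray(keep)]
    programs = [p for p in programs if len(p.genes)]
    programs.insert(0, GeneProgram("plaque", [driver_gene], 2.0,
                                   driver_fold))
    xy = tissue[["x_px", "y_px"]].to_numpy()
    centers = xy[rng.choice(len(xy), size=n_blobs, replace=False)]
    field_vals = np.zeros(len(xy))
    for c in centers:
        d2 = ((xy - c) ** 2).sum(axis=1)
        field_vals += np.exp(-d2 / (2 * blob_sigma_px ** 2))
    field_vals /= field_vals.max()
    act_field = default_activation_field()
    sdata = simulate_counts(tissue, programs, act_field, genotype="AD",
                            age="7M", sample="AD-7M-rep1",
                            activation_override={"plaque": field_vals},
                            seed=seed + 1)
    return sdata


# ---------------------------------------------------------------------------
# plaque-like image rendering


@dataclass
class PlaqueImage:
    """A rendered (and optionally deranged) plaque-like image plus truth."""

    image: np.ndarray            # the moving image handed to registration
    clean: np.ndarray            # noiseless image in the spot (fixed) frame
    spot_amplitude: np.ndarray   # per-spot splat amplitude (driver log-expr)
    landmarks_moving: np.ndarray
    landmarks_fixed: np.ndarray
    true_transform: TransformChain
    driver_gene: str


def render_plaque_image(sdata: SyntheticDataset, driver_gene: str, *,
                        image_shape: tuple[int, int] | None = None,
                        psf_sigma: float = 3.0, noise_sd: float = 0.02,
                        derange: Transform | None = None,
                        n_landmarks: int = 8, seed: int = 0) -> PlaqueImage:
    """Render a grayscale plaque-like image tracking a driver gene.

    Intensity is a Gaussian-blurred splat field: each spot deposits
    ``log1p(driver counts)`` at its pixel position, the field is blurred
    with ``psf_sigma``, normalized to [0, 1], Gaussian read noise is added
    and the result clipped.  ``derange`` (a transform mapping
    moving-image coordinates to the spot frame) then resamples the image
    into a deranged "moving" frame; landmark pairs (moving, fixed) at spot
    positions are returned for registration scoring.
    """
    if not psf_sigma > 0:
        raise ValueError("psf_sigma must be > 0")
    data = sdata.data
    if data.n_spots == 0:
        raise ValueError("dataset has no spots")
    gi = data.gene_index([driver_gene])[0]
    driver = np.asarray(data.counts[gi].todense()).ravel()
    amp = np.log1p(driver)

    xy = data.positions[["x_px", "y_px"]].to_numpy()
    if image_shape is None:
        image_shape = (int(np.ceil(xy[:, 1].max())) + 8,
                       int(np.ceil(xy[:, 0].max())) + 8)
    canvas = np.zeros(image_shape, dtype=float)
    px = np.clip(np.round(xy[:, 0]).astype(int), 0, image_shape[1] - 1)
    py = np.clip(np.round(xy[:, 1]).astype(int), 0, image_shape[0] - 1)
    np.add.at(canvas, (py, px), amp)
    canvas = gaussian_filter(canvas, psf_sigma)
    if canvas.max() > 0:
        canvas = canvas / canvas.max()
    clean = canvas
    rng = np.random.default_rng(seed)
    noisy = clean.copy()
    if noise_sd > 0:
        noisy = np.clip(noisy + rng.normal(0, noise_sd, clean.shape), 0, 1)

    if derange is None:
        chain = identity_chain()
    elif isinstance(derange, TransformChain):
        chain = derange
    else:
        chain = TransformChain([derange])
    from .transforms import warp_image
    moving = np.clip(warp_image(noisy, chain, image_shape), 0, 1)

    # well-spread landmarks: extreme + quantile spots by (x + y) and (x - y)
    order = np.argsort(xy[:, 0] + xy[:, 1])
    order2 = np.argsort(xy[:, 0] - xy[:, 1])
    picks: list = []
    for arr in (order, order2):
        for q in np.linspace(0, 1, max(2, n_landmarks // 2)):
            idx = int(arr[int(q * (len(arr) - 1))])
            if idx not in picks:
                picks.append(idx)
    fixed_pts = xy[picks[:max(4, n_landmarks)]]
    moving_pts = chain.inverse().apply(fixed_pts)
    return PlaqueImage(moving, clean, amp, moving_pts, fixed_pts, chain,
                       driver_gene)
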