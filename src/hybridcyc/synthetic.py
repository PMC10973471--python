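"""Ground-truthed synthetic specimens for the hybrid-cell pipeline.

Emulates the study design at desk scale: two patient-matched specimen types
(a tumor tissue section and a peripheral-blood PBMC preparation), a
14-marker / 4-round staining panel, log-normal per-cell intensities
(multiplicative microscopy noise), rare cancer-immune hybrid cells
(co-expressing CD45 and the epithelial cocktail) partitioned into
subpopulations with distinct marker mean vectors, a fraction of
autofluorescent cells visible in the round-0 background scan, rigid
inter-round stage drift, and optional residual signal carried over from the
previous staining round (incomplete fluorophore erasure).

Every generator is deterministic for a fixed seed, and each returns the
single-cell table together with a row-aligned ground-truth table so that
downstream stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
import yaml

from .errors import DimensionError, GenerationError
from .layout import EPITHELIAL_COCKTAIL, LEUKOCYTE_MARKER, RoundLayout, default_layout

CLASSES = ("epithelial", "leukocyte", "stromal", "hybrid")

#: Baseline (unstained) intensity level, arbitrary fluorescence units.
BACKGROUND_LEVEL = 50.0
#: Intensity of a positively expressed marker (10x background).
POSITIVE_LEVEL = 500.0
#: DAPI nuclear counterstain level.
DAPI_LEVEL = 200.0
#: Round-0 autofluorescence level of an ordinary cell.
ROUND0_LEVEL = 20.0

#: Typical cell areas in px^2 (radius ~9 px tumor cell, ~5 px PBMC).
AREA_LEVELS = {"epithelial": 254.0, "leukocyte": 78.0, "stromal": 180.0, "hybrid": 254.0}

#: Phenotyping-marker pairs used to give hybrid subpopulations distinct
#: mean vectors.  The first pair (VIM/aSMA, the mesenchymal program) is the
#: default cross-compartment shared phenotype.
SUBPOP_MARKER_PAIRS = (
    ("VIM", "aSMA"),
    ("CD44", "Ki67"),
    ("CK8", "CK19"),
    ("EGFR", "CK7"),
    ("pAKT", "VWF"),
)

VALIDATION_CONDITIONS = ("indirect_if", "aboligo_secondary", "aboligo_is", "uv_cleaved", "is_only")
STAINED_CONDITIONS = ("indirect_if", "aboligo_secondary", "aboligo_is")


def marker_column(marker: str, compartment: str) -> str:
    return f"{marker}_{compartment}"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Composition and intensity model of one synthetic specimen.

    ``base_log_means`` (class x marker) and ``subpop_log_means``
    (subpop x marker) are natural-log intensity means; per-cell marker
    intensities are drawn log-normally with scale ``log_sd`` around the mean
    of the cell's class (or hybrid subpopulation).
    """

    n_cells: int
    specimen_type: str  # "tissue" | "blood"
    class_fractions: dict
    base_log_means: pd.DataFrame
    subpop_log_means: pd.DataFrame
    n_hybrid_subpops: int = 1
    log_sd: float = 0.25
    autofluorescent_fraction: float = 0.02
    autofluorescence_multiplier: float = 5.0
    dapi_log_mean: float = math.log(DAPI_LEVEL)
    round0_log_mean: float = math.log(ROUND0_LEVEL)
    area_log_means: dict = field(default_factory=lambda: {k: math.log(v) for k, v in AREA_LEVELS.items()})
    area_log_sd: float = 0.1
    specimen_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.specimen_type not in ("tissue", "blood"):
            raise GenerationError(f"unknown specimen_type {self.specimen_type!r}")
        if self.n_cells < 1:
            raise GenerationError("n_cells must be >= 1")
        fr = self.class_fractions
        if set(fr) - set(CLASSES):
            raise GenerationError(f"unknown classes: {set(fr) - set(CLASSES)}")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"class_fractions sum to {total}, expected 1")
        if any(not (0.0 <= f <= 1.0) for f in fr.values()):
            raise GenerationError("class fractions must lie in [0, 1]")
        if fr.get("hybrid", 0.0) > 0 and self.n_hybrid_subpops < 1:
            raise GenerationError("n_hybrid_subpops must be >= 1 when hybrids are present")
        if self.log_sd <= 0:
            raise GenerationError("log_sd must be positive")
        if not (0.0 <= self.autofluorescent_fraction <= 1.0):
            raise GenerationError("autofluorescent_fraction must lie in [0, 1]")
        if not self.base_log_means.columns.equals(self.subpop_log_means.columns):
            raise DimensionError("base and subpop mean matrices disagree on markers")
        if len(self.subpop_log_means) < self.n_hybrid_subpops:
            raise DimensionError("subpop_log_means has fewer rows than n_hybrid_subpops")

    @property
    def markers(self) -> list:
        return list(self.base_log_means.columns)


def default_base_log_means(
    layout: RoundLayout | None = None,
    background: float = BACKGROUND_LEVEL,
    positive: float = POSITIVE_LEVEL,
) -> pd.DataFrame:
    """Class-level log-intensity means for the default panel.

    Epithelial cells express the epithelial cocktail and cytokeratins;
    leukocytes express CD45; stromal cells express aSMA and VIM; hybrids
    co-express CD45 plus the epithelial cocktail (the defining phenotype).
    """
    layout = layout or default_layout()
    markers = layout.marker_names
    lo, hi = math.log(background), math.log(positive)
    df = pd.DataFrame(lo, index=list(CLASSES), columns=markers, dtype=float)
    epithelial_on = list(EPITHELIAL_COCKTAIL) + [m for m in ("CK19", "CK8", "CK7") if m in markers]
    df.loc["epithelial", epithelial_on] = hi
    df.loc["leukocyte", LEUKOCYTE_MARKER] = hi
    df.loc["stromal", [m for m in ("aSMA", "VIM") if m in markers]] = hi
    df.loc["hybrid", list(EPITHELIAL_COCKTAIL) + [LEUKOCYTE_MARKER]] = hi
    return df


def default_subpop_log_means(
    n_subpops: int,
    layout: RoundLayout | None = None,
    marker_pairs=None,
    background: float = BACKGROUND_LEVEL,
    positive: float = POSITIVE_LEVEL,
    pair_levels=None,
) -> pd.DataFrame:
    """Hybrid-subpopulation mean vectors: the hybrid base phenotype plus a
    distinct pair of elevated phenotyping markers per subpopulation.

    ``pair_levels`` optionally sets a per-subpopulation elevation (AU) for
    its marker pair, e.g. to make one phenotype more strongly expressed."""
    layout = layout or default_layout()
    pairs = list(marker_pairs) if marker_pairs is not None else list(SUBPOP_MARKER_PAIRS)
    if n_subpops > len(pairs):
        raise GenerationError(f"need {n_subpops} marker pairs, have {len(pairs)}")
    levels = list(pair_levels) if pair_levels is not None else [positive] * n_subpops
    base = default_base_log_means(layout, background, positive).loc["hybrid"]
    rows = []
    for s in range(n_subpops):
        row = base.copy()
        for m in pairs[s]:
            if m not in row.index:
                raise DimensionError(f"subpop marker {m!r} not in panel")
            row[m] = math.log(levels[s])
        rows.append(row)
    return pd.DataFrame(rows, index=[f"sub{s}" for s in range(n_subpops)])


#: Subpopulation marker pairs of the matched synthetic patient: disjoint
#: pairs within each compartment (near-equidistant mean vectors), with the
#: mesenchymal VIM/aSMA phenotype planted in both compartments.
TISSUE_SUBPOP_PAIRS = (("VIM", "aSMA"), ("CD44", "Ki67"), ("CK8", "CK19"), ("EGFR", "CK7"))
# blood's non-shared pairs recombine markers that also occur in tissue
# subpopulations (balanced pooled z-scale) without duplicating any tissue
# pair vector
BLOOD_SUBPOP_PAIRS = (("VIM", "aSMA"), ("CD44", "CK19"), ("EGFR", "Ki67"))
#: The shared phenotype is the most strongly expressed (1.6x the others),
#: mirroring a dominant conserved mesenchymal program.
SHARED_PAIR_LEVEL = 800.0


def matched_patient_configs(
    tissue_n: int = 50_000,
    blood_n: int = 20_000,
    tissue_hybrid_fraction: float = 0.008,
    blood_hybrid_fraction: float = 0.002,
    log_sd: float = 0.08,
    seed: int = 0,
    layout: RoundLayout | None = None,
) -> tuple[PopulationConfig, PopulationConfig]:
    """Patient-matched tissue + blood configs with a planted shared phenotype.

    Four tissue and three blood hybrid subpopulations; the first
    subpopulation of each compartment carries the same elevated VIM/aSMA
    mean vector, so exactly one cross-compartment cluster pair should be
    strongly correlated.  The tight ``log_sd`` makes the gating markers
    separable at these population sizes (see docs for the design argument).
    """
    layout = layout or default_layout()
    t_levels = [SHARED_PAIR_LEVEL] + [POSITIVE_LEVEL] * (len(TISSUE_SUBPOP_PAIRS) - 1)
    b_levels = [SHARED_PAIR_LEVEL] + [POSITIVE_LEVEL] * (len(BLOOD_SUBPOP_PAIRS) - 1)
    t_cfg = tissue_population_config(
        n_cells=tissue_n,
        hybrid_fraction=tissue_hybrid_fraction,
        n_hybrid_subpops=len(TISSUE_SUBPOP_PAIRS),
        seed=seed,
        layout=layout,
        subpop_marker_pairs=TISSUE_SUBPOP_PAIRS,
        log_sd=log_sd,
    )
    t_cfg.subpop_log_means = default_subpop_log_means(
        len(TISSUE_SUBPOP_PAIRS), layout, TISSUE_SUBPOP_PAIRS, pair_levels=t_levels
    )
    b_cfg = blood_population_config(
        n_cells=blood_n,
        hybrid_fraction=blood_hybrid_fraction,
        n_hybrid_subpops=len(BLOOD_SUBPOP_PAIRS),
        seed=seed + 1,
        layout=layout,
        subpop_marker_pairs=BLOOD_SUBPOP_PAIRS,
        log_sd=log_sd,
    )
    b_cfg.subpop_log_means = default_subpop_log_means(
        len(BLOOD_SUBPOP_PAIRS), layout, BLOOD_SUBPOP_PAIRS, pair_levels=b_levels
    )
    return t_cfg, b_cfg


def tissue_population_config(
    n_cells: int = 5000,
    hybrid_fraction: float = 0.0083,
    n_hybrid_subpops: int = 4,
    seed: int = 0,
    layout: RoundLayout | None = None,
    subpop_marker_pairs=None,
    specimen_id: str = "tissue1",
    **kwargs,
) -> PopulationConfig:
    """Tumor-tissue composition: epithelial-dominated with infiltrating
    leukocytes and stroma; hybrid prevalence defaults to the sub-percent
    regime (0.83%) observed in tumor sections."""
    layout = layout or default_layout()
    rest = 1.0 - hybrid_fraction
    fr = {
        "epithelial": 0.60 * rest,
        "leukocyte": 0.25 * rest,
        "stromal": 0.15 * rest,
        "hybrid": hybrid_fraction,
    }
    return PopulationConfig(
        n_cells=n_cells,
        specimen_type="tissue",
        class_fractions=fr,
        base_log_means=default_base_log_means(layout),
        subpop_log_means=default_subpop_log_means(n_hybrid_subpops, layout, subpop_marker_pairs),
        n_hybrid_subpops=n_hybrid_subpops,
        specimen_id=specimen_id,
        seed=seed,
        **kwargs,
    )


def blood_population_config(
    n_cells: int = 2000,
    hybrid_fraction: float = 0.0015,
    n_hybrid_subpops: int = 3,
    seed: int = 1,
    layout: RoundLayout | None = None,
    subpop_marker_pairs=None,
    specimen_id: str = "blood1",
    **kwargs,
) -> PopulationConfig:
    """PBMC-preparation composition: leukocyte-dominated with rare
    epithelial (CTC-like) cells and rarer hybrids (0.15% default)."""
    layout = layout or default_layout()
    fr = {
        "epithelial": min(0.005, 1.0 - hybrid_fraction),
        "stromal": 0.0,
        "hybrid": hybrid_fraction,
    }
    fr["leukocyte"] = 1.0 - sum(fr.values())
    return PopulationConfig(
        n_cells=n_cells,
        specimen_type="blood",
        class_fractions=fr,
        base_log_means=default_base_log_means(layout),
        subpop_log_means=default_subpop_log_means(n_hybrid_subpops, layout, subpop_marker_pairs),
        n_hybrid_subpops=n_hybrid_subpops,
        specimen_id=specimen_id,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def generate_cell_population(
    config: PopulationConfig,
    layout: RoundLayout | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a single-cell intensity table and its row-aligned ground truth.

    The first draw from the seeded generator is the class assignment
    (``rng.choice`` over classes with the configured fractions), so an
    independent re-draw with the same seed reproduces the class sample.
    Intensities are log-normal around the class / subpopulation mean; the
    table carries one column per marker and compartment
    (``<marker>_whole_cell`` etc.), the round-0 autofluorescence mean, and
    cell areas.  Positions (``x``, ``y``) are filled by
    :func:`place_cells` / :func:`render_image_rounds` and are NaN here.
    """
    layout = layout or default_layout()
    if list(config.base_log_means.columns) != layout.marker_names:
        raise DimensionError(
            "config mean matrices and layout disagree on the marker set: "
            f"{list(config.base_log_means.columns)} vs {layout.marker_names}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    class_names = list(CLASSES)
    p = np.array([config.class_fractions.get(c, 0.0) for c in class_names])
    true_class = rng.choice(class_names, size=n, p=p)
    is_hybrid = true_class == "hybrid"
    subpop = np.full(n, -1)
    subpop[is_hybrid] = rng.integers(0, config.n_hybrid_subpops, size=is_hybrid.sum())

    markers = config.markers
    log_means = config.base_log_means.loc[true_class].to_numpy()
    if is_hybrid.any():
        log_means[is_hybrid] = config.subpop_log_means.to_numpy()[subpop[is_hybrid]]
    intensities = np.exp(rng.normal(log_means, config.log_sd))

    dapi = np.exp(rng.normal(config.dapi_log_mean, config.log_sd, size=n))
    is_af = rng.random(n) < config.autofluorescent_fraction
    r0_mu = config.round0_log_mean + np.where(is_af, math.log(config.autofluorescence_multiplier), 0.0)
    round0 = np.exp(rng.normal(r0_mu, config.log_sd))
    area_mu = np.array([config.area_log_means[c] for c in true_class])
    area = np.exp(rng.normal(area_mu, config.area_log_sd))

    cell_ids = [f"{config.specimen_id}_c{i:06d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "specimen_id": config.specimen_id,
            "specimen_type": config.specimen_type,
            "x": np.nan,
            "y": np.nan,
            "area": area,
        }
    )
    for j, m in enumerate(markers):
        for comp in ("whole_cell", "nucleus", "cytoplasm"):
            table[marker_column(m, comp)] = intensities[:, j]
    table["round0_mean"] = round0
    table["dapi_mean"] = dapi
    table["qc_flags"] = ""

    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "true_class": true_class,
            "true_subpop": [f"sub{s}" if s >= 0 else "" for s in subpop],
            "x": np.nan,
            "y": np.nan,
            "is_autofluorescent": is_af,
        }
    )
    return table, truth


def generate_unstained_control(
    n_cells: int = 500,
    layout: RoundLayout | None = None,
    specimen_type: str = "tissue",
    specimen_id: str = "control",
    background: float = BACKGROUND_LEVEL,
    log_sd: float = 0.25,
    seed: int = 99,
) -> pd.DataFrame:
    """An unstained-control table: every marker at background level.

    Used to derive per-marker positivity thresholds (gating normalizes to
    an unstained control)."""
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    n = n_cells
    table = pd.DataFrame(
        {
            "cell_id": [f"{specimen_id}_c{i:06d}" for i in range(n)],
            "specimen_id": specimen_id,
            "specimen_type": specimen_type,
            "x": np.nan,
            "y": np.nan,
            "area": np.exp(rng.normal(math.log(AREA_LEVELS["epithelial"]), 0.1, size=n)),
        }
    )
    for m in layout.marker_names:
        vals = np.exp(rng.normal(math.log(background), log_sd, size=n))
        for comp in ("whole_cell", "nucleus", "cytoplasm"):
            table[marker_column(m, comp)] = vals
    table["round0_mean"] = np.exp(rng.normal(math.log(ROUND0_LEVEL), log_sd, size=n))
    table["dapi_mean"] = np.exp(rng.normal(math.log(DAPI_LEVEL), log_sd, size=n))
    table["qc_flags"] = ""
    return table


# ---------------------------------------------------------------------------
# validation specimens (blood model / staining-condition contrasts)
# ---------------------------------------------------------------------------

def generate_validation_specimen(
    marker: str,
    positive_population: str,
    condition: str,
    layout: RoundLayout | None = None,
    n_cancer: int = 40,
    n_pbmc: int = 80,
    contrast: float = 5.0,
    background: float = BACKGROUND_LEVEL,
    log_sd: float = 0.15,
    seed: int = 0,
    specimen_id: str = "val",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A two-population blood-model specimen for staining validation.

    Cancer cells are notably larger than PBMCs (they are identified by
    size downstream).  Under the stained conditions the configured positive
    population carries ``contrast`` x background intensity for ``marker``;
    under ``uv_cleaved`` and ``is_only`` both populations sit at background.
    ``positive_population`` may be ``cancer``, ``pbmc``, ``both`` (a
    dual-staining marker like CD44/aSMA) or ``none`` (a marker that stains
    neither population, like VWF in this panel).
    """
    layout = layout or default_layout()
    if marker not in layout:
        raise DimensionError(f"marker {marker!r} not in layout")
    if condition not in VALIDATION_CONDITIONS:
        raise GenerationError(f"unknown condition {condition!r}")
    if positive_population not in ("cancer", "pbmc", "both", "none"):
        raise GenerationError(f"unknown positive_population {positive_population!r}")

    rng = np.random.default_rng(seed)
    n = n_cancer + n_pbmc
    population = np.array(["cancer"] * n_cancer + ["pbmc"] * n_pbmc)
    stained = condition in STAINED_CONDITIONS
    if positive_population == "both":
        is_positive = np.ones(n, dtype=bool)
    elif positive_population == "none":
        is_positive = np.zeros(n, dtype=bool)
    else:
        is_positive = population == positive_population

    area_mu = np.where(population == "cancer", math.log(AREA_LEVELS["epithelial"]), math.log(AREA_LEVELS["leukocyte"]))
    table = pd.DataFrame(
        {
            "cell_id": [f"{specimen_id}_c{i:04d}" for i in range(n)],
            "specimen_id": specimen_id,
            "specimen_type": "blood",
            "x": np.nan,
            "y": np.nan,
            "area": np.exp(rng.normal(area_mu, 0.1)),
            "population_label": population,
        }
    )
    for m in layout.marker_names:
        mu = np.full(n, math.log(background))
        if m == marker and stained:
            mu[is_positive] = math.log(contrast * background)
        vals = np.exp(rng.normal(mu, log_sd))
        for comp in ("whole_cell", "nucleus", "cytoplasm"):
            table[marker_column(m, comp)] = vals
    table["round0_mean"] = np.exp(rng.normal(math.log(ROUND0_LEVEL), log_sd, size=n))
    table["dapi_mean"] = np.exp(rng.normal(math.log(DAPI_LEVEL), log_sd, size=n))
    # anticipated-pattern annotation used by tissue-mode S:B positive-cell
    # selection (the manual-annotation import path)
    table["is_positive"] = is_positive & stained
    table["qc_flags"] = ""

    truth = pd.DataFrame(
        {
            "cell_id": table["cell_id"],
            "true_class": population,
            "true_subpop": "",
            "x": np.nan,
            "y": np.nan,
            "is_autofluorescent": False,
            "is_positive": is_positive & stained,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderConfig:
    """Geometry and physics of the rendered image stacks.

    ``round_shifts`` lists one (dy, dx) rigid drift per round *including*
    round 0; ``residual_signal_fraction`` scales how much of the previous
    round's marker signal survives UV erasure into the same fluorophore
    channel of the next round.
    """

    image_shape: tuple = (256, 256)
    nucleus_radius: int = 4
    cell_radius: int = 9
    round_shifts: list = None
    psf_sigma: float = 0.0
    noise_model: str = "none"  # none | poisson | gaussian
    noise_sigma: float = 2.0
    residual_signal_fraction: float = 0.0
    min_spacing_factor: float = 2.0
    max_placement_tries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.cell_radius > self.nucleus_radius > 0):
            raise GenerationError("require cell_radius > nucleus_radius > 0")
        if not (0.0 <= self.residual_signal_fraction <= 1.0):
            raise GenerationError("residual_signal_fraction must lie in [0, 1]")
        if self.psf_sigma < 0:
            raise GenerationError("psf_sigma must be >= 0")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise GenerationError(f"unknown noise model {self.noise_model!r}")

    def shifts_for(self, rounds: list) -> dict:
        if self.round_shifts is None:
            return {r: (0.0, 0.0) for r in rounds}
        if len(self.round_shifts) != len(rounds):
            raise DimensionError(
                f"round_shifts has {len(self.round_shifts)} entries for {len(rounds)} rounds"
            )
        return {r: tuple(s) for r, s in zip(rounds, self.round_shifts)}


def place_cells(
    n: int,
    rc: RenderConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Poisson-disk (dart-throwing) placement of ``n`` cell centers.

    Enforces pairwise spacing >= ``min_spacing_factor * cell_radius`` and a
    border margin of one cell radius so rendered cells never merge or fall
    off the frame.  Raises :class:`GenerationError` when the frame cannot
    accommodate ``n`` cells at that spacing.
    """
    rng = rng if rng is not None else np.random.default_rng(rc.seed)
    h, w = rc.image_shape
    margin = rc.cell_radius
    min_dist = rc.min_spacing_factor * rc.cell_radius
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise GenerationError("image too small for the configured cell radius")

    # grid acceleration: bins of min_dist so only 3x3 neighborhoods are checked
    gy = max(1, int(np.ceil((h) / min_dist)))
    gx = max(1, int(np.ceil((w) / min_dist)))
    grid: dict = {}
    centers = np.empty((n, 2), dtype=float)
    placed = 0
    tries_per_cell = rc.max_placement_tries
    for i in range(n):
        for _ in range(tries_per_cell):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            by, bx = int(y / min_dist), int(x / min_dist)
            ok = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for j in grid.get((by + dy, bx + dx), ()):
                        if (centers[j, 0] - y) ** 2 + (centers[j, 1] - x) ** 2 < min_dist**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                centers[i] = (y, x)
                grid.setdefault((by, bx), []).append(i)
                placed += 1
                break
        else:
            raise GenerationError(
                f"could not place cell {i + 1}/{n} after {tries_per_cell} tries; "
                "enlarge the image or reduce spacing"
            )
    del gy, gx
    return centers


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = yy**2 + xx**2 <= r**2
    return yy[keep], xx[keep]


def _paint(canvas: np.ndarray, centers: np.ndarray, values: np.ndarray, offsets) -> None:
    oy, ox = offsets
    h, w = canvas.shape
    for (cy, cx), v in zip(centers, values):
        ys = np.rint(cy).astype(int) + oy
        xs = np.rint(cx).astype(int) + ox
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        canvas[ys[keep], xs[keep]] = v


def render_image_rounds(
    table: pd.DataFrame,
    truth: pd.DataFrame,
    layout: RoundLayout | None = None,
    rc: RenderConfig | None = None,
) -> tuple[dict, dict]:
    """Render per-round multi-channel image stacks from a cell table.

    Each cell is a nucleus disk (DAPI and nucleus-compartment markers) inside
    a whole-cell disk (all other markers); round 0 carries only the
    autofluorescence background channel; every round is translated by its
    configured rigid drift; a ``residual_signal_fraction`` of the previous
    round's marker signal leaks into the same fluorophore channel of the
    next round.  If positions are missing they are drawn by
    :func:`place_cells` (and written back into ``table`` and ``truth``).

    Returns ``(stacks, channels)``: ``stacks[round]`` is a float
    ``(C, H, W)`` array and ``channels[round]`` the matching channel names.
    """
    layout = layout or default_layout()
    rc = rc or RenderConfig()
    rng = np.random.default_rng(rc.seed)

    if truth["x"].isna().any():
        # positions are written back into the caller's table and truth so
        # they stay row-aligned with the rendered stacks
        centers = place_cells(len(table), rc, rng)
        table.loc[:, "y"], table.loc[:, "x"] = centers[:, 0], centers[:, 1]
        truth.loc[:, "y"], truth.loc[:, "x"] = centers[:, 0], centers[:, 1]
    else:
        centers = truth[["y", "x"]].to_numpy(dtype=float)
    h, w = rc.image_shape
    margin_ok = (
        (centers[:, 0] >= rc.cell_radius)
        & (centers[:, 0] <= h - rc.cell_radius)
        & (centers[:, 1] >= rc.cell_radius)
        & (centers[:, 1] <= w - rc.cell_radius)
    )
    if not margin_ok.all():
        raise GenerationError("cell centers fall outside the frame margin")

    nuc_off = _disk_offsets(rc.nucleus_radius)
    cell_off = _disk_offsets(rc.cell_radius)
    rounds = [layout.background_round] + layout.rounds
    shifts = rc.shifts_for(rounds)

    dapi_vals = table["dapi_mean"].to_numpy(dtype=float)
    stacks: dict = {}
    channel_names: dict = {}
    prev_pure: dict = {}  # channel -> pure marker image of the previous round
    for r in rounds:
        chans = layout.channels_in_round(r)
        imgs = []
        this_pure: dict = {}
        for ch in chans:
            canvas = np.zeros((h, w), dtype=float)
            if ch == layout.nuclear_channel:
                _paint(canvas, centers, dapi_vals, nuc_off)
            elif r == layout.background_round and ch == layout.background_channel:
                _paint(canvas, centers, table["round0_mean"].to_numpy(dtype=float), cell_off)
            else:
                mk = next(m for m in layout.markers_in_round(r) if m.channel == ch)
                vals = table[marker_column(mk.name, "whole_cell")].to_numpy(dtype=float)
                offsets = nuc_off if mk.compartment == "nucleus" else cell_off
                _paint(canvas, centers, vals, offsets)
                this_pure[ch] = canvas.copy()
                if rc.residual_signal_fraction > 0 and ch in prev_pure:
                    canvas = canvas + rc.residual_signal_fraction * prev_pure[ch]
            imgs.append(canvas)
        prev_pure = this_pure

        stack = np.stack(imgs)
        if rc.psf_sigma > 0:
            stack = ndi.gaussian_filter(stack, sigma=(0, rc.psf_sigma, rc.psf_sigma))
        dy, dx = shifts[r]
        if dy or dx:
            stack = ndi.shift(stack, (0, dy, dx), order=1, cval=0.0, prefilter=False)
        if rc.noise_model == "gaussian":
            stack = stack + rng.normal(0.0, rc.noise_sigma, size=stack.shape)
            stack = np.clip(stack, 0, None)
        elif rc.noise_model == "poisson":
            stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
        stacks[r] = stack
        channel_names[r] = chans
    return stacks, channel_names


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def write_image_rounds(outdir, stacks: dict, channels: dict) -> None:
    """Write one multi-channel TIFF per round plus a YAML channel sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {}
    for r, stack in stacks.items():
        name = f"round_{r}.tif"
        tifffile.imwrite(outdir / name, stack, photometric="minisblack")
        meta[name] = {"round": int(r), "channels": list(channels[r])}
    with open(outdir / "channels.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_image_rounds(indir) -> tuple[dict, dict]:
    """Read stacks written by :func:`write_image_rounds`."""
    from pathlib import Path

    indir = Path(indir)
    with open(indir / "channels.yaml") as fh:
        meta = yaml.safe_load(fh)
    stacks, channels = {}, {}
    for name, info in meta.items():
        r = int(info["round"])
        stacks[r] = tifffile.imread(indir / name)
        channels[r] = list(info["channels"])
    return stacks, channels
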