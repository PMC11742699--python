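"""Synthetic cohorts and IR scenes with known ground truth.

The human-tissue data behind this workflow are not publicly deposited, so
every downstream stage is exercised against synthetic stand-ins:

* a species-level lipidome cohort generator calibrated, at the
  double-bond-bin and total-carbon-bin level, to the printed composition
  anchors of the study (8 AD cases contributing paired plaque/surrounding
  samples plus 8 healthy-control samples), and
* an IR hyperspectral scene generator producing FTIR- or QCL-gridded
  absorbance cubes with Gaussian vibrational bands, Mie-like scatter
  baselines, i.i.d. noise, and plaque lesions with a depressed alkene band
  and an amide-I beta-sheet shift -- together with pixel-true masks.

Calibration happens at run time and is fully deterministic: the mean joint
(carbon, double-bond) table is obtained by iterative proportional fitting
(IPF) of a plausibility seed to the configured marginals, and the
plaque-minus-surrounding and control-offset tables are minimum-norm least
squares solutions with the PC 32:0 cell pinned to its configured species
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ir import SpectralImage
from .lipidomics import DB_BINS, CARBON_BINS, LipidomeSample, samples_to_frame

__all__ = [
    "CohortConfig",
    "CohortCalibrationError",
    "SpeciesPanelEntry",
    "CohortCalibration",
    "default_cohort_config",
    "calibrate_cohort",
    "build_species_panel",
    "generate_lipidome_cohort",
    "Band",
    "Lesion",
    "IRSceneConfig",
    "generate_ir_scene",
    "ftir_grid",
    "qcl_grid",
    "DEFAULT_BAND_TABLE",
]

GROUPS = ("plaque", "surrounding", "control")

# --------------------------------------------------------------------------
# Default calibration anchors.
#
# Group marginals over double-bond bins 0-7 and even total-carbon bins
# 30-44 (mol%, each row sums to 100).  The printed group means (saturated
# 11 +- 2 over all samples, UFA 88 +- 1 in plaques vs 91 +- 1 in
# surrounding) and the paired saturated-lipid effect (+1.6 +- 0.5) cannot
# all hold as exact equalities; the defaults below place the plaque/
# surrounding UFA means at 88.6 / 90.2 so the paired effect is exactly
# +1.6 while every group mean stays within its printed SD.  Unprinted bins
# are free parameters chosen once for a realistic gray-matter lipidome
# (abundant monounsaturated species; polyunsaturated mass concentrated in
# arachidonoyl- and docosahexaenoyl-containing 36-40 carbon species).
# --------------------------------------------------------------------------

_DB_TARGETS = {
    "plaque":      {0: 11.40, 1: 36.35, 2: 14.10, 3: 1.25, 4: 12.95, 5: 6.10, 6: 14.10, 7: 3.75},
    "surrounding": {0: 9.80,  1: 36.45, 2: 15.90, 3: 1.35, 4: 13.05, 5: 5.90, 6: 13.90, 7: 3.65},
    "control":     {0: 11.80, 1: 35.20, 2: 15.00, 3: 1.30, 4: 13.00, 5: 6.00, 6: 14.00, 7: 3.70},
}

_CARBON_TARGETS = {
    "plaque":      {30: 1.10, 32: 12.80, 34: 23.00, 36: 18.15, 38: 18.40, 40: 12.40, 42: 9.90, 44: 4.25},
    "surrounding": {30: 0.60, 32: 10.90, 34: 21.90, 36: 18.85, 38: 19.60, 40: 12.60, 42: 10.50, 44: 5.05},
    "control":     {30: 0.85, 32: 11.85, 34: 22.45, 36: 18.50, 38: 19.00, 40: 12.50, 42: 10.20, 44: 4.65},
}

# Documented paired plaque-minus-surrounding anchors (mean, SD) in
# percentage points; means must agree with the marginal differences above.
_PAIRED_EFFECTS = {
    "db": {0: (1.6, 0.5), 2: (-1.8, 0.9)},
    "carbon": {32: (1.9, 0.6)},
}
_SPECIES_EFFECTS = {"PC 32:0": (1.8, 0.6)}

# Chemically allowed double-bond range per total-carbon bin (a 30-carbon
# chain pair cannot carry 6 double bonds) and a plausibility seed for IPF.
_MAX_DB = {30: 2, 32: 3, 34: 4, 36: 5, 38: 6, 40: 7, 42: 7, 44: 7}

_SEED_JOINT = {
    30: {0: 0.5, 1: 0.4, 2: 0.1},
    32: {0: 6.0, 1: 4.0, 2: 1.0, 3: 0.2},
    34: {0: 3.0, 1: 12.0, 2: 4.0, 3: 0.3, 4: 0.5},
    36: {0: 1.0, 1: 8.0, 2: 5.0, 3: 0.4, 4: 3.0, 5: 1.0},
    38: {0: 0.3, 1: 2.0, 2: 2.0, 3: 0.3, 4: 6.0, 5: 1.5, 6: 6.0},
    40: {0: 0.1, 1: 1.0, 2: 1.5, 3: 0.2, 4: 2.0, 5: 1.5, 6: 6.0, 7: 1.5},
    42: {0: 0.1, 1: 3.0, 2: 2.5, 3: 0.2, 4: 1.0, 5: 1.0, 6: 1.5, 7: 1.5},
    44: {0: 0.05, 1: 0.5, 2: 0.5, 3: 0.1, 4: 1.0, 5: 1.0, 6: 0.8, 7: 0.8},
}


class CohortCalibrationError(ValueError):
    """The configured targets cannot be realized as a valid composition."""


@dataclass
class CohortConfig:
    """Configuration of the synthetic lipidome cohort.

    Noise model: per-case and per-sample logistic-normal perturbations of
    the joint (carbon, double-bond) cell masses (log-scale SDs
    ``case_noise_sd`` / ``sample_noise_sd`` for AD tissue, ``hc_noise_sd``
    for control tissue -- the control scale is deliberately larger,
    emulating the broad spread of manually selected gray-matter regions),
    plus a per-case scalar effect size g ~ N(1, ``paired_effect_rel_sd``)
    multiplying the calibrated plaque-minus-surrounding difference table.
    ``noise_sd_scale`` scales every noise source at once; zero reproduces
    the targets exactly.
    """

    n_ad_cases: int = 8
    n_hc_cases: int = 8
    group_db_targets: dict = field(default_factory=lambda: {g: dict(v) for g, v in _DB_TARGETS.items()})
    group_carbon_targets: dict = field(default_factory=lambda: {g: dict(v) for g, v in _CARBON_TARGETS.items()})
    paired_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in _PAIRED_EFFECTS.items()})
    species_effects: dict = field(default_factory=lambda: dict(_SPECIES_EFFECTS))
    paired_effect_rel_sd: float = 0.33
    case_noise_sd: float = 0.035
    sample_noise_sd: float = 0.02
    hc_noise_sd: float = 0.12
    noise_sd_scale: float = 1.0
    lyso_fraction: float = 0.02
    labeled_fraction: float = 0.01
    total_pmol: float = 2000.0
    total_pmol_log_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_ad_cases < 1 or self.n_hc_cases < 0:
            raise CohortCalibrationError("need at least one AD case")
        for name, targets, bins in (
                ("db", self.group_db_targets, DB_BINS),
                ("carbon", self.group_carbon_targets, CARBON_BINS)):
            for g in GROUPS:
                if g not in targets:
                    raise CohortCalibrationError(f"missing {name} targets for group {g!r}")
                vals = targets[g]
                if any(v < 0 for v in vals.values()):
                    raise CohortCalibrationError(f"negative {name} target in group {g!r}")
                total = sum(vals.get(b, 0.0) for b in bins)
                if abs(total - 100.0) > 1e-6:
                    raise CohortCalibrationError(
                        f"{name} targets for {g!r} sum to {total}, not 100")
        for table, anchors in self.paired_effects.items():
            targets = {"db": self.group_db_targets, "carbon": self.group_carbon_targets}[table]
            for b, (mean, sd) in anchors.items():
                if sd < 0:
                    raise CohortCalibrationError("negative paired-effect SD")
                diff = targets["plaque"].get(b, 0.0) - targets["surrounding"].get(b, 0.0)
                if abs(diff - mean) > 1e-9:
                    raise CohortCalibrationError(
                        f"paired effect for {table} bin {b} ({mean}) inconsistent "
                        f"with group targets (difference {diff})")
        for sd_name in ("paired_effect_rel_sd", "case_noise_sd", "sample_noise_sd",
                        "hc_noise_sd", "noise_sd_scale", "lyso_fraction",
                        "labeled_fraction", "total_pmol_log_sd"):
            if getattr(self, sd_name) < 0:
                raise CohortCalibrationError(f"{sd_name} must be nonnegative")


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default calibrated cohort configuration (see module docstring)."""
    return replace(CohortConfig(seed=seed), **overrides)


@dataclass(frozen=True)
class SpeciesPanelEntry:
    """One species of the synthetic panel: identity plus its share of the
    mean composition (``base_weight``; the panel's weights sum to 1)."""

    species_name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    base_weight: float


def _cell_class_weights(c: int, db: int) -> dict[str, float]:
    """Within-cell lipid-class split (fixed across tissue groups)."""
    if (c, db) == (32, 0):
        return {"PC": 0.9, "PE": 0.1}
    w = {"PC": 0.45, "PE": 0.25}
    if db <= 3:
        w["SM"] = 0.08
        w["Cer"] = 0.04
    if db <= 2 and c >= 40:
        w["HexCer"] = 0.02
    if c >= 36:
        w["PS"] = 0.08
        if db >= 2:
            w["PI"] = 0.06
    if db <= 4:
        w["PC O"] = 0.04
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def _species_name(cls: str, c: int, db: int) -> str:
    return f"PC O-{c}:{db}" if cls == "PC O" else f"{cls} {c}:{db}"


def _ipf(seed: np.ndarray, row_targets: np.ndarray, col_targets: np.ndarray,
         tol: float = 1e-12, max_iter: int = 20000) -> np.ndarray:
    """Iterative proportional fitting of a nonnegative table to marginals."""
    if abs(row_targets.sum() - col_targets.sum()) > 1e-9:
        raise CohortCalibrationError("marginal totals disagree")
    T = seed.astype(float).copy()
    for _ in range(max_iter):
        rs = T.sum(axis=1)
        np.divide(row_targets, rs, out=rs, where=rs > 0)
        T *= rs[:, None]
        cs = T.sum(axis=0)
        np.divide(col_targets, cs, out=cs, where=cs > 0)
        T *= cs[None, :]
        err = max(np.abs(T.sum(axis=1) - row_targets).max(),
                  np.abs(T.sum(axis=0) - col_targets).max())
        if err < tol:
            return T
    raise CohortCalibrationError(
        "IPF did not converge; the configured marginals are infeasible on "
        "the chemically allowed (carbon, double-bond) support")


def _min_norm_table(
    free: np.ndarray,
    row_sums: np.ndarray,
    col_sums: np.ndarray,
    pinned: dict[tuple[int, int], float],
    mass: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted minimum-norm table with prescribed marginals.

    Solves for the cell adjustments with the given row and column sums,
    minimizing ``sum(x_c^2 / m_c)`` so well-populated cells absorb most of
    the reallocation and small cells are barely touched.
    """
    n_r, n_c = free.shape
    rs = row_sums.astype(float).copy()
    cs = col_sums.astype(float).copy()
    out = np.zeros((n_r, n_c))
    for (i, j), v in pinned.items():
        out[i, j] = v
        rs[i] -= v
        cs[j] -= v
    if abs(rs.sum() - cs.sum()) > 1e-9:
        raise CohortCalibrationError("inconsistent marginal sums")
    idx = [(i, j) for i in range(n_r) for j in range(n_c)
           if free[i, j] and (i, j) not in pinned]
    A = np.zeros((n_r + n_c, len(idx)))
    for k, (i, j) in enumerate(idx):
        A[i, k] = 1.0
        A[n_r + j, k] = 1.0
    w = (np.ones(len(idx)) if mass is None
         else np.sqrt([max(mass[i, j], 1e-9) for i, j in idx]))
    b = np.concatenate([rs, cs])
    y, *_ = np.linalg.lstsq(A * w[None, :], b, rcond=None)
    x = w * y
    if np.linalg.norm(A @ x - b) > 1e-8:
        raise CohortCalibrationError(
            "marginal difference targets are infeasible on the free support")
    for k, (i, j) in enumerate(idx):
        out[i, j] = x[k]
    return out


@dataclass
class CohortCalibration:
    """Joint (carbon, double-bond) mol% targets and the species panel."""

    carbons: tuple[int, ...]
    dbs: tuple[int, ...]
    support: np.ndarray
    mean_joint: np.ndarray
    diff_joint: np.ndarray
    group_joints: dict[str, np.ndarray]
    panel: list[SpeciesPanelEntry]
    panel_cells: list[tuple[int, int]]
    panel_weights: np.ndarray


def calibrate_cohort(config: CohortConfig) -> CohortCalibration:
    """Derive joint composition targets and the species panel.

    The mean joint table is IPF-fitted to the across-group mean marginals;
    the paired-difference table D (row sums = carbon-bin effects, column
    sums = double-bond effects, PC 32:0 cell pinned) and the control offset
    table G are minimum-norm least-squares solutions on well-populated
    cells.  Group joints are mean -/+ half the difference table (control =
    mean + G).  Raises ``CohortCalibrationError`` if any resulting cell is
    negative or a populated bin has no species.
    """
    config.validate()
    carbons, dbs = CARBON_BINS, DB_BINS
    n_r, n_c = len(carbons), len(dbs)
    support = np.zeros((n_r, n_c), dtype=bool)
    seed = np.zeros((n_r, n_c))
    for i, c in enumerate(carbons):
        for j, db in enumerate(dbs):
            if db <= _MAX_DB[c]:
                support[i, j] = True
                seed[i, j] = _SEED_JOINT[c].get(db, 0.0) or 1e-6

    def marg(targets, bins):
        return {g: np.array([targets[g].get(b, 0.0) for b in bins]) for g in GROUPS}

    row_m = marg(config.group_carbon_targets, carbons)
    col_m = marg(config.group_db_targets, dbs)
    row_mean = sum(row_m[g] for g in GROUPS) / 3.0
    col_mean = sum(col_m[g] for g in GROUPS) / 3.0
    M = _ipf(seed, row_mean, col_mean)

    # Cells free to carry group differences: the better-populated part of
    # each carbon row, so small cells are never driven negative.
    row_max = M.max(axis=1, keepdims=True)
    col_max = M.max(axis=0, keepdims=True)
    free = support & ((M >= 0.3 * row_max) | (M >= 0.3 * col_max) | (M >= 1.0))

    pinned: dict[tuple[int, int], float] = {}
    for name, (mean, _sd) in config.species_effects.items():
        from .lipidomics import parse_shorthand
        sp = parse_shorthand(name)
        if sp.total_carbons not in carbons or sp.total_double_bonds not in dbs:
            raise CohortCalibrationError(f"species effect {name!r} outside bins")
        i = carbons.index(sp.total_carbons)
        j = dbs.index(sp.total_double_bonds)
        cell_w = _cell_class_weights(sp.total_carbons, sp.total_double_bonds)
        w = cell_w.get(sp.lipid_class, 0.0)
        if w <= 0:
            raise CohortCalibrationError(
                f"species {name!r} has zero weight in its cell")
        pinned[(i, j)] = mean / w

    d_row = row_m["plaque"] - row_m["surrounding"]
    d_col = col_m["plaque"] - col_m["surrounding"]
    D = _min_norm_table(free, d_row, d_col, pinned, mass=M)
    # control = mean + G  =>  G marginals are control minus mean marginals
    g_row = row_m["control"] - row_mean
    g_col = col_m["control"] - col_mean
    G = _min_norm_table(free, g_row, g_col, {}, mass=M)

    S = M - (D + G) / 2.0
    joints = {"surrounding": S, "plaque": S + D, "control": M + G}
    for g, J in joints.items():
        bad = (J < -1e-9) & support
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortCalibrationError(
                f"negative target after effect application: group {g!r}, "
                f"bin ({carbons[i]}:{dbs[j]})")
        joints[g] = np.clip(J, 0.0, None) * support

    # Species panel from the mean joint.
    panel: list[SpeciesPanelEntry] = []
    cells: list[tuple[int, int]] = []
    weights: list[float] = []
    for i, c in enumerate(carbons):
        for j, db in enumerate(dbs):
            if not support[i, j] or M[i, j] <= 1e-9:
                continue
            for cls, w in _cell_class_weights(c, db).items():
                panel.append(SpeciesPanelEntry(
                    species_name=_species_name(cls, c, db),
                    lipid_class=cls,
                    total_carbons=c,
                    total_double_bonds=db,
                    base_weight=M[i, j] / 100.0 * w,
                ))
                cells.append((i, j))
                weights.append(w)

    covered_c = {carbons[i] for i, j in cells}
    covered_db = {dbs[j] for i, j in cells}
    for g in GROUPS:
        for b, v in config.group_carbon_targets[g].items():
            if v > 0 and b not in covered_c:
                raise CohortCalibrationError(
                    f"carbon bin {b} has target mass but no species in the panel")
        for b, v in config.group_db_targets[g].items():
            if v > 0 and b not in covered_db:
                raise CohortCalibrationError(
                    f"double-bond bin {b} has target mass but no species in the panel")

    return CohortCalibration(
        carbons=carbons, dbs=dbs, support=support, mean_joint=M,
        diff_joint=D, group_joints=joints, panel=panel,
        panel_cells=cells, panel_weights=np.array(weights),
    )


def build_species_panel(config: CohortConfig | None = None) -> list[SpeciesPanelEntry]:
    """The deterministic species panel implied by a cohort configuration."""
    return calibrate_cohort(config or default_cohort_config()).panel


# Fixed spiked species so the exclusion stage has realistic work to do.
_LYSO_SPIKES = (("LPC 16:0", 0.6), ("LPE 18:1", 0.4))
_LABELED_SPIKE = "SM 18:1;O2/18:1[D9]"


def generate_lipidome_cohort(
    config: CohortConfig | None = None,
    *,
    return_frame: bool = False,
):
    """Generate the synthetic lipidome cohort.

    Returns ``n_ad_cases`` paired plaque/surrounding samples plus
    ``n_hc_cases`` control samples as :class:`LipidomeSample` objects (or,
    with ``return_frame=True``, the long CSV-schema table).  With
    ``noise_sd_scale=0`` every sample's aggregate profile equals its group
    target exactly; otherwise expected aggregates equal the targets up to
    second-order logistic-normal bias.
    """
    config = config or default_cohort_config()
    cal = calibrate_cohort(config)
    rng = np.random.default_rng(config.seed)
    scale = config.noise_sd_scale

    flat = cal.support.ravel()
    s_cells = cal.group_joints["surrounding"].ravel()[flat]
    d_cells = cal.diff_joint.ravel()[flat]
    c_cells = cal.group_joints["control"].ravel()[flat]
    cell_index = {cell: k for k, cell in enumerate(
        [tuple(ij) for ij in np.argwhere(cal.support)])}
    panel_cell_idx = np.array([cell_index[c] for c in cal.panel_cells])
    n_cells = s_cells.size

    def renorm(mass: np.ndarray) -> np.ndarray:
        mass = np.maximum(mass, 1e-9)
        return 100.0 * mass / mass.sum()

    def sample_total() -> float:
        return config.total_pmol * float(
            np.exp(scale * config.total_pmol_log_sd * rng.standard_normal()))

    def to_sample(sid: str, cid: str, group: str, mass: np.ndarray) -> LipidomeSample:
        total = sample_total()
        conc: dict[str, float] = {}
        species_mass = mass[panel_cell_idx] * cal.panel_weights
        for entry, m in zip(cal.panel, species_mass):
            conc[entry.species_name] = total * m / 100.0
        if config.lyso_fraction > 0:
            for name, share in _LYSO_SPIKES:
                conc[name] = total * config.lyso_fraction * share
        if config.labeled_fraction > 0:
            conc[_LABELED_SPIKE] = total * config.labeled_fraction
        return LipidomeSample(sid, cid, group, conc)

    samples: list[LipidomeSample] = []
    for i in range(config.n_ad_cases):
        cid = f"AD{i + 1:02d}"
        z = rng.standard_normal(n_cells)
        e_s = rng.standard_normal(n_cells)
        e_p = rng.standard_normal(n_cells)
        g_i = 1.0 + scale * config.paired_effect_rel_sd * rng.standard_normal()
        g_i = float(np.clip(g_i, 0.0, 2.0))
        case_log = scale * config.case_noise_sd * z
        s_mass = renorm(s_cells * np.exp(case_log + scale * config.sample_noise_sd * e_s))
        p_base = renorm(s_cells * np.exp(case_log + scale * config.sample_noise_sd * e_p))
        p_mass = renorm(p_base + g_i * d_cells)
        samples.append(to_sample(f"{cid}-plaque", cid, "plaque", p_mass))
        samples.append(to_sample(f"{cid}-surrounding", cid, "surrounding", s_mass))
    for i in range(config.n_hc_cases):
        cid = f"HC{i + 1:02d}"
        z = rng.standard_normal(n_cells)
        mass = renorm(c_cells * np.exp(scale * config.hc_noise_sd * z))
        samples.append(to_sample(f"{cid}-gm", cid, "control", mass))

    if return_frame:
        return samples_to_frame(samples)
    return samples


# ---------------------------------------------------------------------------
# IR hyperspectral scenes
# ---------------------------------------------------------------------------

def ftir_grid() -> np.ndarray:
    """FTIR wavenumber grid: 948-3700 cm^-1 at 1.9 cm^-1 sampling."""
    return np.arange(948.0, 3700.0 + 1e-9, 1.9)


def qcl_grid() -> np.ndarray:
    """QCL-IR wavenumber grid: 948-1800 cm^-1 at 2 cm^-1 sampling."""
    return np.arange(948.0, 1800.0 + 1e-9, 2.0)


@dataclass(frozen=True)
class Band:
    """A Gaussian vibrational band: peak height above zero baseline."""

    center: float
    width: float  # Gaussian sigma, cm^-1
    amplitude: float


# Tissue-like band table: C-H stretches, the alkene =C-H stretch (3012),
# the ester C=O stretch (1738), amide I (1655 helix / 1630 beta-sheet)
# and amide II.
DEFAULT_BAND_TABLE: tuple[Band, ...] = (
    Band(2850.0, 10.0, 0.25),
    Band(2920.0, 12.0, 0.40),
    Band(2960.0, 10.0, 0.20),
    Band(3012.0, 8.0, 0.05),
    Band(1738.0, 10.0, 0.30),
    Band(1655.0, 14.0, 0.80),
    Band(1630.0, 12.0, 0.30),
    Band(1545.0, 14.0, 0.50),
)

ALKENE_CENTER = 3012.0
AMIDE_SHEET_CENTER = 1630.0


@dataclass(frozen=True)
class Lesion:
    """A circular plaque lesion: alkene depression + amide-I shift."""

    center: tuple[float, float]  # (row, col) in pixels
    radius_um: float
    alkene_scale: float = 0.6
    amide1630_scale: float = 1.5

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("lesion radius must be positive")
        if not (0 < self.alkene_scale <= 1):
            raise ValueError("alkene_scale must be in (0, 1]")
        if self.amide1630_scale < 1:
            raise ValueError("amide1630_scale must be >= 1")


@dataclass
class IRSceneConfig:
    """Configuration of a synthetic IR hyperspectral scene."""

    grid: str = "FTIR"
    image_shape: tuple[int, int] | None = None
    pixel_size: float | None = None
    band_table: tuple[Band, ...] = DEFAULT_BAND_TABLE
    plaque_lesions: tuple[Lesion, ...] = ()
    scatter_amplitude: float = 0.0
    scatter_hotspots: tuple[tuple[tuple[int, int], float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def resolved(self) -> tuple[np.ndarray, tuple[int, int], float]:
        grid = self.grid.upper()
        if grid == "FTIR":
            wn, shape, px = ftir_grid(), (128, 128), 1.1
        elif grid == "QCL":
            wn, shape, px = qcl_grid(), (480, 480), 4.25
        else:
            raise ValueError(f"unknown grid {self.grid!r} (FTIR or QCL)")
        if self.image_shape is not None:
            shape = tuple(self.image_shape)
        if self.pixel_size is not None:
            px = float(self.pixel_size)
        return wn, shape, px


def generate_ir_scene(config: IRSceneConfig) -> tuple[SpectralImage, dict]:
    """Generate an IR scene and its pixel-true ground truth.

    The cube is an additive Gaussian-band model plus an optional smooth
    sinusoid-and-slope scatter baseline (a stand-in for Mie ripple, not a
    physical Mie model) and i.i.d. Gaussian noise.  Inside each lesion the
    alkene band amplitude is multiplied by ``alkene_scale`` and the
    1630 cm^-1 amide-I component by ``amide1630_scale``.

    Returns the :class:`SpectralImage` and a ground-truth dict with the
    boolean ``plaque_mask``, synthetic ``core_stain`` / ``corona_stain``
    images (stand-ins for fibril-core and anti-amyloid antibody channels),
    and the per-pixel ``alkene_scale_map`` / ``amide_scale_map``.
    """
    wn, (h, w), px = config.resolved()
    rng = np.random.default_rng(config.seed)

    rows, cols = np.mgrid[0:h, 0:w]
    plaque_mask = np.zeros((h, w), dtype=bool)
    core_mask = np.zeros((h, w), dtype=bool)
    alkene_map = np.ones((h, w))
    amide_map = np.ones((h, w))
    for lesion in config.plaque_lesions:
        ci, cj = lesion.center
        r_px = lesion.radius_um / px
        if (ci - r_px < -0.5 or ci + r_px > h - 0.5
                or cj - r_px < -0.5 or cj + r_px > w - 0.5):
            raise ValueError(f"lesion at {lesion.center} extends outside the image")
        disc = (rows - ci) ** 2 + (cols - cj) ** 2 <= r_px ** 2
        plaque_mask |= disc
        core_mask |= (rows - ci) ** 2 + (cols - cj) ** 2 <= (r_px / 2.0) ** 2
        alkene_map = np.where(disc, np.minimum(alkene_map, lesion.alkene_scale),
                              alkene_map)
        amide_map = np.where(disc, np.maximum(amide_map, lesion.amide1630_scale),
                             amide_map)

    cube = np.zeros((h, w, wn.size))
    for band in config.band_table:
        if not (wn[0] <= band.center <= wn[-1]):
            continue
        profile = band.amplitude * np.exp(-((wn - band.center) ** 2)
                                          / (2.0 * band.width ** 2))
        if band.center == ALKENE_CENTER:
            cube += alkene_map[..., None] * profile
        elif band.center == AMIDE_SHEET_CENTER:
            cube += amide_map[..., None] * profile
        else:
            cube += profile

    if config.scatter_amplitude > 0 or config.scatter_hotspots:
        lam = (wn - wn[0]) / (wn[-1] - wn[0])
        amp = config.scatter_amplitude * rng.uniform(0.5, 1.5, size=(h, w))
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(h, w))
        slope = rng.uniform(-0.5, 0.5, size=(h, w))
        for (r, c), a in config.scatter_hotspots:
            amp[r, c] = a
        cube += amp[..., None] * (
            np.sin(2.0 * np.pi * 1.5 * lam + phase[..., None])
            + slope[..., None] * lam)

    if config.noise_sd > 0:
        cube += rng.normal(0.0, config.noise_sd, size=cube.shape)

    image = SpectralImage(wavenumbers=wn, absorbance=cube, pixel_size=px,
                          provenance="synthetic")
    corona_mask = plaque_mask & ~core_mask
    truth = {
        "plaque_mask": plaque_mask,
        "core_stain": np.where(core_mask, 1.0, 0.02),
        "corona_stain": np.where(plaque_mask, 1.0, 0.02),
        "alkene_scale_map": alkene_map,
        "amide_scale_map": amide_map,
        "corona_mask": corona_mask,
    }
    return image, truth
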