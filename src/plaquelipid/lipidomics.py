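"""Species-level lipidome composition analysis.

Shotgun (FIA-MS style) lipidomics yields molar concentrations of lipid
species annotated in shorthand sum notation (e.g. ``PC 32:0`` = a
phosphatidylcholine whose two acyl chains together contain 32 carbons and
0 C=C double bonds).  This module parses those names, normalizes each
sample to molar composition (mol%), aggregates composition over
double-bond and total-acyl-carbon bins, and provides the group statistics
used to contrast plaque, surrounding and control tissue: paired per-case
differences, Welch's t-test, standardized (SVD) PCA, a linear SVM
separator, and species correlation matrices.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LipidParseError",
    "LipidSpecies",
    "LipidomeSample",
    "CompositionProfile",
    "GroupDifferenceProfile",
    "PCAResult",
    "LinearSeparator",
    "CorrelationResult",
    "parse_shorthand",
    "exclude_species",
    "normalize_molar",
    "composition_profile",
    "cohort_composition",
    "group_difference_profile",
    "group_welch_profile",
    "welch_t",
    "pca_standardized",
    "fit_linear_separator",
    "species_correlation_matrix",
    "samples_from_frame",
    "samples_to_frame",
    "DB_BINS",
    "CARBON_BINS",
]

# Reported binning of the composition profiles: lipids carry 0-7 C=C double
# bonds and 30-44 (even) total acyl carbons; anything outside is kept in an
# overflow bucket rather than silently renormalized away.
DB_BINS: tuple[int, ...] = tuple(range(0, 8))
CARBON_BINS: tuple[int, ...] = tuple(range(30, 46, 2))

_KNOWN_CLASSES = {"PC", "PE", "PS", "PI", "SM", "Cer", "HexCer", "LPC", "LPE"}
_LYSO_CLASSES = {"LPC", "LPE"}

_CHAIN_RE = re.compile(r"^(\d+):(\d+)(;O\d*)?(\[D\d+\])?$")
_LABEL_RE = re.compile(r"\[D\d+\]")


class LipidParseError(ValueError):
    """Raised when a lipid shorthand name cannot be interpreted."""


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species at sum-composition resolution."""

    name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    is_lyso: bool
    is_labeled_standard: bool

    def __post_init__(self) -> None:
        if self.total_carbons <= 0:
            raise LipidParseError(f"{self.name!r}: non-positive carbon count")
        if self.total_double_bonds < 0:
            raise LipidParseError(f"{self.name!r}: negative double-bond count")


def parse_shorthand(name: str) -> LipidSpecies:
    """Parse a lipid shorthand name into class, carbons and double bonds.

    Handles sum notation (``PC 32:0``), chain-level notation
    (``PE 14:0/14:0``), sphingolipids with hydroxyl annotation
    (``Cer 18:1;O2/14:0``), isotope-labeled standards (``...[D9]``) and
    ether lipids (``PC O-34:1``).  Carbons and double bonds are summed over
    all chain tokens, so the sphingoid-base double bond of sphingolipids is
    counted (``Cer 18:1;O2/14:0`` has 1 double bond); see the methods note.

    Raises
    ------
    LipidParseError
        If the name has no chain token or an unrecognizable token.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    cleaned = re.sub(r"\s*\([^)]*\)\s*$", "", name.strip())
    first_chain = re.search(r"\d+:\d+", cleaned)
    if first_chain is None:
        raise LipidParseError(f"{name!r}: no chain token (expected 'C:D')")
    head = cleaned[: first_chain.start()].strip()
    chain_str = cleaned[first_chain.start():].strip()

    ether = False
    head_tokens = head.replace("-", " ").split()
    if head_tokens and head_tokens[-1] == "O":
        ether = True
        head_tokens = head_tokens[:-1]
    class_token = " ".join(head_tokens)
    if not class_token:
        raise LipidParseError(f"{name!r}: missing lipid class token")

    carbons = 0
    double_bonds = 0
    for token in chain_str.split("/"):
        m = _CHAIN_RE.match(token.strip())
        if m is None:
            raise LipidParseError(f"{name!r}: unrecognized chain token {token!r}")
        carbons += int(m.group(1))
        double_bonds += int(m.group(2))

    if class_token in _KNOWN_CLASSES:
        lipid_class = f"{class_token} O" if ether else class_token
    else:
        lipid_class = "other"
    return LipidSpecies(
        name=name.strip(),
        lipid_class=lipid_class,
        total_carbons=carbons,
        total_double_bonds=double_bonds,
        is_lyso=class_token in _LYSO_CLASSES,
        is_labeled_standard=bool(_LABEL_RE.search(cleaned)),
    )


@dataclass
class LipidomeSample:
    """Molar concentrations of lipid species for one LMD sample.

    ``tissue_group`` is one of ``plaque``, ``surrounding``, ``control``;
    plaque and surrounding samples from the same AD case share a
    ``case_id`` and form a pair.
    """

    sample_id: str
    case_id: str
    tissue_group: str
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if self.tissue_group not in {"plaque", "surrounding", "control"}:
            raise ValueError(f"unknown tissue group {self.tissue_group!r}")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("negative species concentration")


def samples_from_frame(df: pd.DataFrame) -> list[LipidomeSample]:
    """Load samples from the long cohort table.

    Expected columns: ``sample_id, case_id, tissue_group, species_name,
    concentration_pmol``.
    """
    required = {"sample_id", "case_id", "tissue_group", "species_name",
                "concentration_pmol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    samples = []
    for (sid, cid, grp), sub in df.groupby(
            ["sample_id", "case_id", "tissue_group"], sort=True):
        conc = dict(zip(sub["species_name"], sub["concentration_pmol"].astype(float)))
        samples.append(LipidomeSample(str(sid), str(cid), str(grp), conc))
    return samples


def samples_to_frame(samples: Iterable[LipidomeSample]) -> pd.DataFrame:
    rows = [
        (s.sample_id, s.case_id, s.tissue_group, name, conc)
        for s in samples
        for name, conc in sorted(s.concentrations.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "case_id", "tissue_group", "species_name",
                 "concentration_pmol"],
    )


def exclude_species(
    sample: LipidomeSample,
    *,
    drop_lyso: bool = True,
    drop_labeled: bool = True,
) -> LipidomeSample:
    """Drop lysophospholipids and isotope-labeled standards from a sample.

    Lysophospholipids carry a single acyl chain and are not comparable with
    the two-chain species analyzed here; labeled species are spiked internal
    standards, not tissue lipids.  The removed molar fraction is reported via
    a ``UserWarning`` when it exceeds 10% of the total.
    """
    kept: dict[str, float] = {}
    removed = 0.0
    for name, conc in sample.concentrations.items():
        sp = parse_shorthand(name)
        if (drop_lyso and sp.is_lyso) or (drop_labeled and sp.is_labeled_standard):
            removed += conc
        else:
            kept[name] = conc
    total = removed + sum(kept.values())
    if not kept or sum(kept.values()) <= 0:
        raise ValueError(
            f"sample {sample.sample_id}: no analyzable species after exclusion")
    if total > 0 and removed / total > 0.10:
        warnings.warn(
            f"sample {sample.sample_id}: excluded {100 * removed / total:.1f}% "
            "of molar content (lyso / labeled standards)",
            stacklevel=2,
        )
    return LipidomeSample(sample.sample_id, sample.case_id, sample.tissue_group, kept)


def normalize_molar(sample: LipidomeSample) -> pd.Series:
    """Normalize a sample to mol% of total molar lipid content."""
    conc = pd.Series(sample.concentrations, dtype=float).sort_index()
    total = conc.sum()
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id}: zero total concentration")
    return 100.0 * conc / total


@dataclass
class CompositionProfile:
    """Mol% distributions over double-bond and total-carbon bins.

    ``db_fraction`` maps double-bond counts 0-7 to mol%, ``carbon_fraction``
    maps even total-carbon bins 30-44 to mol%.  Species falling outside a
    bin range accumulate in the ``*_overflow`` fields and are *not*
    renormalized away, so each reported map plus its overflow sums to 100.
    """

    db_fraction: dict[int, float]
    carbon_fraction: dict[int, float]
    db_overflow: float
    carbon_overflow: float
    ufa_percent: float
    mean_chain_length: float


def composition_profile(sample: LipidomeSample) -> CompositionProfile:
    """Aggregate a sample's mol% over double-bond and carbon bins.

    ``ufa_percent`` is 100 minus the fully saturated (DB=0) fraction;
    ``mean_chain_length`` is the mol%-weighted mean of the total acyl carbon
    number over the reported 30-44 bins.
    """
    molpct = normalize_molar(sample)
    db = {b: 0.0 for b in DB_BINS}
    carbon = {b: 0.0 for b in CARBON_BINS}
    db_over = 0.0
    carbon_over = 0.0
    for name, pct in molpct.items():
        sp = parse_shorthand(name)
        if sp.total_double_bonds in db:
            db[sp.total_double_bonds] += pct
        else:
            db_over += pct
        if sp.total_carbons in carbon:
            carbon[sp.total_carbons] += pct
        else:
            carbon_over += pct
    mean_len = sum(c * f for c, f in carbon.items()) / 100.0
    return CompositionProfile(
        db_fraction=db,
        carbon_fraction=carbon,
        db_overflow=db_over,
        carbon_overflow=carbon_over,
        ufa_percent=100.0 - db[0],
        mean_chain_length=mean_len,
    )


def cohort_composition(
    samples: Sequence[LipidomeSample],
    *,
    apply_exclusion: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species mol% matrix and per-sample metadata for a cohort.

    Returns ``(composition, meta)`` where ``composition`` is a
    sample x species mol% table (absent species = 0) and ``meta`` holds
    ``case_id`` and ``tissue_group`` indexed like ``composition``.
    """
    if not samples:
        raise ValueError("empty cohort")
    rows = {}
    meta_rows = {}
    for s in samples:
        s2 = exclude_species(s) if apply_exclusion else s
        rows[s.sample_id] = normalize_molar(s2)
        meta_rows[s.sample_id] = {"case_id": s.case_id,
                                  "tissue_group": s.tissue_group}
    comp = pd.DataFrame(rows).T.fillna(0.0).sort_index()
    comp = comp[sorted(comp.columns)]
    meta = pd.DataFrame(meta_rows).T.loc[comp.index]
    return comp, meta


def _profile_tables(
    samples: Sequence[LipidomeSample],
    apply_exclusion: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample DB-bin, carbon-bin and species mol% tables plus metadata."""
    comp, meta = cohort_composition(samples, apply_exclusion=apply_exclusion)
    species = [parse_shorthand(c) for c in comp.columns]
    db_cols = pd.Series([sp.total_double_bonds for sp in species], index=comp.columns)
    c_cols = pd.Series([sp.total_carbons for sp in species], index=comp.columns)
    db_tab = comp.T.groupby(db_cols).sum().T.reindex(columns=DB_BINS, fill_value=0.0)
    c_tab = comp.T.groupby(c_cols).sum().T.reindex(columns=CARBON_BINS, fill_value=0.0)
    return db_tab, c_tab, comp, meta


@dataclass
class GroupDifferenceProfile:
    """Paired plaque-minus-surrounding differences, per AD case.

    Each ``per_case_*`` table has one row per paired case (percentage
    points); the ``db``/``carbon``/``species`` summaries report the mean and
    SD over cases.  Per-bin differences sum to zero within each case because
    both compositions sum to 100.
    """

    per_case_db: pd.DataFrame
    per_case_carbon: pd.DataFrame
    per_case_species: pd.DataFrame
    db: pd.DataFrame
    carbon: pd.DataFrame
    species: pd.DataFrame


def group_difference_profile(
    samples: Sequence[LipidomeSample],
    *,
    apply_exclusion: bool = True,
) -> GroupDifferenceProfile:
    """Compute paired per-case plaque-minus-surrounding difference profiles.

    Cases lacking either member of the pair are excluded with a warning.
    Requires at least two complete pairs.
    """
    db_tab, c_tab, comp, meta = _profile_tables(samples, apply_exclusion)
    plaque = meta[meta["tissue_group"] == "plaque"].set_index("case_id")
    surr = meta[meta["tissue_group"] == "surrounding"].set_index("case_id")
    cases = sorted(set(plaque.index) & set(surr.index))
    orphans = (set(plaque.index) | set(surr.index)) - set(cases)
    if orphans:
        warnings.warn(f"unpaired cases excluded: {sorted(orphans)}", stacklevel=2)
    if len(cases) < 2:
        raise ValueError("need at least two paired plaque/surrounding cases")

    def paired(tab: pd.DataFrame) -> pd.DataFrame:
        rows = {}
        for case in cases:
            p_id = meta[(meta["case_id"] == case)
                        & (meta["tissue_group"] == "plaque")].index[0]
            s_id = meta[(meta["case_id"] == case)
                        & (meta["tissue_group"] == "surrounding")].index[0]
            rows[case] = tab.loc[p_id] - tab.loc[s_id]
        return pd.DataFrame(rows).T

    def summarize(per_case: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_diff": per_case.mean(axis=0),
            "sd": per_case.std(axis=0, ddof=1),
        })

    pc_db, pc_c, pc_sp = paired(db_tab), paired(c_tab), paired(comp)
    return GroupDifferenceProfile(
        per_case_db=pc_db,
        per_case_carbon=pc_c,
        per_case_species=pc_sp,
        db=summarize(pc_db),
        carbon=summarize(pc_c),
        species=summarize(pc_sp),
    )


def group_welch_profile(
    samples: Sequence[LipidomeSample],
    group_a: str,
    group_b: str,
    *,
    table: str = "db",
    apply_exclusion: bool = True,
) -> pd.DataFrame:
    """Unpaired per-bin Welch contrasts between two tissue groups.

    ``table`` selects ``db`` or ``carbon`` binning.  Returns a per-bin frame
    with group means, their difference, and Welch (t, df, p); no
    multiple-testing adjustment is applied.
    """
    db_tab, c_tab, _, meta = _profile_tables(samples, apply_exclusion)
    tab = {"db": db_tab, "carbon": c_tab}[table]
    a = tab.loc[meta["tissue_group"] == group_a]
    b = tab.loc[meta["tissue_group"] == group_b]
    rows = []
    for col in tab.columns:
        try:
            t, df, p = welch_t(a[col].to_numpy(), b[col].to_numpy())
        except ValueError:
            t, df, p = np.nan, np.nan, np.nan
        rows.append({"bin": col, f"mean_{group_a}": a[col].mean(),
                     f"mean_{group_b}": b[col].mean(),
                     "diff": a[col].mean() - b[col].mean(),
                     "t": t, "df": df, "p": p,
                     "stars": significance_stars(p)})
    return pd.DataFrame(rows).set_index("bin")


def significance_stars(p: float) -> str:
    """Confidence-level notation: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not np.isfinite(p):
        return ""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < threshold:
            return stars
    return "ns"


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test (two-sided).

    Returns ``(t, df, p)`` with t = (m1-m2)/sqrt(s1^2/n1 + s2^2/n2) and the
    Welch-Satterthwaite degrees of freedom.  Raises if either group has
    fewer than two values or both variances are zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two values")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance")
    se2_1, se2_2 = v1 / n1, v2 / n2
    t = (a.mean() - b.mean()) / np.sqrt(se2_1 + se2_2)
    df = (se2_1 + se2_2) ** 2 / (
        se2_1 ** 2 / (n1 - 1) + se2_2 ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class PCAResult:
    """Standardized-SVD PCA: scores, loadings, explained variance."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    dropped_features: list[str] = field(default_factory=list)


def pca_standardized(X: pd.DataFrame) -> PCAResult:
    """PCA of column-standardized data via singular value decomposition.

    Columns are centered and scaled to unit SD (equivalently, the PCA of the
    correlation matrix).  Zero-variance columns are dropped with a warning.
    Component signs follow the convention that each component's
    largest-magnitude loading is positive.
    """
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    sd = X.std(axis=0, ddof=1)
    dropped = list(X.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)",
                      stacklevel=2)
        X = X.drop(columns=dropped)
    if X.shape[1] < 2:
        raise ValueError("need at least two non-constant features")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loadings = Vt.T
    scores = U * S
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    ev = S ** 2 / (X.shape[0] - 1)
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        explained_variance=ev,
        explained_variance_ratio=S ** 2 / np.sum(S ** 2),
        dropped_features=dropped,
    )


@dataclass
class LinearSeparator:
    """Maximum-margin linear boundary w.x + b = 0 in score space."""

    weights: np.ndarray
    offset: float
    training_accuracy: float
    hard_margin: bool

    def decision(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.weights + self.offset


def fit_linear_separator(
    scores: np.ndarray,
    labels: Sequence,
    *,
    penalty: float = 1.0,
) -> LinearSeparator:
    """Fit a linear SVM boundary between two classes of points.

    Attempts a (numerically) hard-margin fit first; if the classes are not
    linearly separable, falls back to a soft margin with the given penalty
    and reports the achieved training accuracy.
    """
    from sklearn.svm import SVC

    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("each class needs at least two points")
    clf = SVC(kernel="linear", C=1e6)
    clf.fit(X, y)
    acc = float(np.mean(clf.predict(X) == y))
    hard = acc == 1.0
    if not hard:
        clf = SVC(kernel="linear", C=penalty)
        clf.fit(X, y)
        acc = float(np.mean(clf.predict(X) == y))
    return LinearSeparator(
        weights=clf.coef_.ravel().copy(),
        offset=float(clf.intercept_[0]),
        training_accuracy=acc,
        hard_margin=hard,
    )


@dataclass
class CorrelationResult:
    """Pearson correlations of anchor species against all species."""

    r: pd.DataFrame
    p: pd.DataFrame


def species_correlation_matrix(
    composition: pd.DataFrame,
    anchor_species: Sequence[str],
    all_species: Sequence[str] | None = None,
) -> CorrelationResult:
    """Pearson R (with two-sided p) of anchor species mol% vs every species.

    ``composition`` is a sample x species mol% table (typically restricted
    to plaque samples).  Self-correlations and zero-variance species are
    masked as NaN.
    """
    if composition.shape[0] < 3:
        raise ValueError("need at least three samples for correlation")
    targets = list(all_species) if all_species is not None else list(composition.columns)
    missing = [a for a in anchor_species if a not in composition.columns]
    if missing:
        raise ValueError(f"anchor species not in composition table: {missing}")
    r = pd.DataFrame(index=list(anchor_species), columns=targets, dtype=float)
    p = pd.DataFrame(index=list(anchor_species), columns=targets, dtype=float)
    for a in anchor_species:
        x = composition[a].to_numpy()
        for t in targets:
            yv = composition[t].to_numpy()
            if a == t or np.std(x) == 0 or np.std(yv) == 0:
                r.loc[a, t] = np.nan
                p.loc[a, t] = np.nan
                continue
            res = stats.pearsonr(x, yv)
            r.loc[a, t] = res.statistic
            p.loc[a, t] = res.pvalue
    return CorrelationResult(r=r, p=p)
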