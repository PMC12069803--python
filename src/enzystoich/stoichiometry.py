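"""Soil C:N:P ratios, enzyme stoichiometry, and the enzyme vector model.

Extracellular enzyme stoichiometry (EES) summarises microbial nutrient
acquisition effort as ratios of log-transformed potential activities of
C-acquiring (βG, CBH), N-acquiring (NAG, LAP) and P-acquiring (ACP)
enzymes:

    EES C:N = ln(βG + CBH) / ln(NAG + LAP)
    EES C:P = ln(βG)       / ln(ACP)
    EES N:P = ln(NAG + LAP) / ln(ACP)

Note the deliberate asymmetry: EES C:P uses βG alone while the vector
x-component below uses βG + CBH.  Under microbial elemental homeostasis
all three ratios sit at the theoretical 1:1:1 reference.

The enzyme vector model places each sample at the point

    x = ln(βG + CBH) / ln(ACP)        (relative C vs P effort)
    y = ln(βG + CBH) / ln(NAG + LAP)  (relative C vs N effort)

Vector length √(x² + y²) indexes relative microbial carbon limitation
(longer = stronger C limitation); the vector angle — the polar angle of
(x, y) from the x axis, so tan(angle) = ln(ACP)/ln(NAG + LAP) — indexes
N vs P limitation: < 45° nitrogen limited, > 45° phosphorus limited.

All logarithms require their argument to exceed 1 (activities in
nmol g⁻¹ h⁻¹): at or below 1 the logs hit zero or flip sign and the
ratios lose meaning.  Table-level operations emit flagged missing rows
for such samples rather than propagating NaN silently.

Because the ratios use unnormalised logs they are sensitive to the
activity unit: rescaling all activities by a common factor changes the
EES values.  Activities are expected in nmol g⁻¹ h⁻¹; a QC warning flag
is attached when activities fall outside [10, 1e5].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: atomic masses used by the optional molar-basis soil ratios
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}

#: limitation labels
N_LIMITED = "N_limited"
P_LIMITED = "P_limited"
THRESHOLD = "threshold"

SEASONS = ("spring", "autumn")
MANAGEMENTS = ("HY", "TS", "XY")  # organic / pollution-free / conventional


class StoichiometryError(ValueError):
    """Raised when inputs violate the log-domain or positivity rules."""


@dataclass(frozen=True)
class EnzymeProfile:
    """Per-sample potential enzyme activities (nmol g⁻¹ h⁻¹) with metadata."""

    sample_id: str
    bg: float
    cbh: float
    nag: float
    lap: float
    acp: float
    season: str | None = None
    management: str | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        for name in ("bg", "cbh", "nag", "lap", "acp"):
            if not math.isfinite(getattr(self, name)):
                raise StoichiometryError(
                    f"{self.sample_id}: activity {name} is not finite")

    def _check_log_domain(self) -> None:
        problems = [name for name, value in [
            ("BG", self.bg), ("BG+CBH", self.bg + self.cbh),
            ("NAG+LAP", self.nag + self.lap), ("ACP", self.acp),
        ] if value <= 1.0]
        if problems:
            raise StoichiometryError(
                f"{self.sample_id}: log argument(s) ≤ 1 for {', '.join(problems)}; "
                "EES ratios undefined (activities must exceed 1 nmol g⁻¹ h⁻¹)")


@dataclass(frozen=True)
class SoilChemistry:
    """SOC, TN and TP concentrations (mg g⁻¹) with sample metadata."""

    sample_id: str
    soc: float
    tn: float
    tp: float
    season: str | None = None
    management: str | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        for name in ("soc", "tn", "tp"):
            if not getattr(self, name) > 0:
                raise StoichiometryError(
                    f"{self.sample_id}: {name} must be strictly positive")


@dataclass
class StoichResult:
    sample_id: str
    soil_cn: float = math.nan
    soil_cp: float = math.nan
    soil_np: float = math.nan
    ees_cn: float = math.nan
    ees_cp: float = math.nan
    ees_np: float = math.nan
    vector_length: float = math.nan
    vector_angle: float = math.nan
    limitation: str | None = None
    season: str | None = None
    management: str | None = None
    site: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def c_limitation_index(self) -> float:
        """Alias: vector length indexes relative microbial C limitation."""
        return self.vector_length


# --- soil elemental ratios ---------------------------------------------------

def soil_cnp_ratios(chem: SoilChemistry, molar: bool = False) -> tuple[float, float, float]:
    """Soil C:N, C:P and N:P ratios (mass basis by default, molar optional)."""
    soc, tn, tp = chem.soc, chem.tn, chem.tp
    if molar:
        soc, tn, tp = (soc / ATOMIC_MASS["C"], tn / ATOMIC_MASS["N"],
                       tp / ATOMIC_MASS["P"])
    return soc / tn, soc / tp, tn / tp


# --- enzyme stoichiometry and the vector model -------------------------------

def ees_ratios(profile: EnzymeProfile) -> tuple[float, float, float]:
    """EES C:N, C:P and N:P ratios of log-transformed activities."""
    profile._check_log_domain()
    ln_c = math.log(profile.bg + profile.cbh)
    ln_n = math.log(profile.nag + profile.lap)
    ln_p = math.log(profile.acp)
    return ln_c / ln_n, math.log(profile.bg) / ln_p, ln_n / ln_p


def vector_components(profile: EnzymeProfile) -> tuple[float, float]:
    """(x, y) of the enzyme vector: x = ln(βG+CBH)/ln(ACP), y = ln(βG+CBH)/ln(NAG+LAP)."""
    profile._check_log_domain()
    ln_c = math.log(profile.bg + profile.cbh)
    return ln_c / math.log(profile.acp), ln_c / math.log(profile.nag + profile.lap)


def vector_length(profile: EnzymeProfile) -> float:
    """√(x² + y²); larger values indicate stronger relative C limitation."""
    x, y = vector_components(profile)
    return math.hypot(x, y)


def vector_angle(profile: EnzymeProfile) -> float:
    """Polar angle of (x, y) in degrees, measured from the x axis.

    Equivalently tan(angle) = ln(ACP)/ln(NAG+LAP).  The published formula
    uses spreadsheet ``ATAN2(x, y)`` whose first argument is the abscissa;
    Python's :func:`math.atan2` takes the ordinate first, so the call here
    is ``atan2(y, x)``.  Only this reading makes high ACP activity yield
    angles above the 45° P-limitation threshold.
    """
    x, y = vector_components(profile)
    return math.degrees(math.atan2(y, x))


def classify_limitation(angle: float, tolerance: float = 1e-9) -> str:
    """Map a vector angle to a nutrient-limitation call.

    Below 45° − tolerance: nitrogen limited; above 45° + tolerance:
    phosphorus limited; within the tolerance band: ``threshold`` (the
    classification is defined by strict inequalities only).
    """
    if angle < 45.0 - tolerance:
        return N_LIMITED
    if angle > 45.0 + tolerance:
        return P_LIMITED
    return THRESHOLD


# --- table-level operations --------------------------------------------------

_META_COLS = ("season", "management", "site")

STOICH_COLUMNS = ["sample_id", "season", "management", "site",
                  "soil_cn", "soil_cp", "soil_np",
                  "ees_cn", "ees_cp", "ees_np",
                  "vector_length", "vector_angle", "limitation", "flags"]


def _unit_flags(profile: EnzymeProfile) -> list[str]:
    acts = [profile.bg, profile.cbh, profile.nag, profile.lap, profile.acp]
    if any(0 < a < 10 for a in acts) or any(a > 1e5 for a in acts):
        return ["unit-scale-warning"]
    return []


def profiles_from_frame(df: pd.DataFrame) -> list[EnzymeProfile]:
    """Build EnzymeProfile objects from an activity table (columns:
    sample_id, bg, cbh, nag, lap, acp and optional season/management/site)."""
    out = []
    for _, row in df.iterrows():
        meta = {m: (str(row[m]) if m in df.columns and pd.notna(row[m]) else None)
                for m in _META_COLS}
        out.append(EnzymeProfile(
            sample_id=str(row["sample_id"]),
            bg=float(row["bg"]), cbh=float(row["cbh"]), nag=float(row["nag"]),
            lap=float(row["lap"]), acp=float(row["acp"]), **meta))
    return out


def chemistry_from_frame(df: pd.DataFrame) -> list[SoilChemistry]:
    out = []
    for _, row in df.iterrows():
        meta = {m: (str(row[m]) if m in df.columns and pd.notna(row[m]) else None)
                for m in _META_COLS}
        out.append(SoilChemistry(
            sample_id=str(row["sample_id"]),
            soc=float(row["soc"]), tn=float(row["tn"]), tp=float(row["tp"]), **meta))
    return out


def stoich_single(profile: EnzymeProfile | None,
                  chem: SoilChemistry | None,
                  molar: bool = False,
                  angle_tolerance: float = 1e-9) -> StoichResult:
    """Full stoichiometric result for one sample; missing halves are flagged."""
    if profile is None and chem is None:
        raise StoichiometryError("need at least one of enzyme profile or chemistry")
    sample_id = profile.sample_id if profile is not None else chem.sample_id
    meta_src = profile if profile is not None else chem
    result = StoichResult(sample_id=sample_id, season=meta_src.season,
                          management=meta_src.management, site=meta_src.site)
    if chem is not None:
        result.soil_cn, result.soil_cp, result.soil_np = soil_cnp_ratios(chem, molar=molar)
    else:
        result.flags.append("chemistry-missing")
    if profile is not None:
        try:
            result.ees_cn, result.ees_cp, result.ees_np = ees_ratios(profile)
            result.vector_length = vector_length(profile)
            result.vector_angle = vector_angle(profile)
            result.limitation = classify_limitation(result.vector_angle, angle_tolerance)
        except StoichiometryError as exc:
            result.flags.append(f"log-domain:{exc}")
        result.flags.extend(_unit_flags(profile))
    else:
        result.flags.append("enzymes-missing")
    return result


def stoich_table(profiles, chemistry, molar: bool = False,
                 angle_tolerance: float = 1e-9) -> pd.DataFrame:
    """Join activities and chemistry by sample_id and compute all metrics.

    Samples present in only one input, or failing the log-domain rule, are
    emitted with missing values and an explanatory flag — never dropped.
    Duplicate sample ids in either input are a hard error.
    """
    prof_map: dict[str, EnzymeProfile] = {}
    for p in profiles:
        if p.sample_id in prof_map:
            raise StoichiometryError(f"duplicate sample_id in profiles: {p.sample_id!r}")
        prof_map[p.sample_id] = p
    chem_map: dict[str, SoilChemistry] = {}
    for c in chemistry:
        if c.sample_id in chem_map:
            raise StoichiometryError(f"duplicate sample_id in chemistry: {c.sample_id!r}")
        chem_map[c.sample_id] = c

    ids = list(prof_map)
    ids += [i for i in chem_map if i not in prof_map]
    rows = []
    for sid in ids:
        res = stoich_single(prof_map.get(sid), chem_map.get(sid),
                            molar=molar, angle_tolerance=angle_tolerance)
        rows.append({
            "sample_id": res.sample_id, "season": res.season,
            "management": res.management, "site": res.site,
            "soil_cn": res.soil_cn, "soil_cp": res.soil_cp, "soil_np": res.soil_np,
            "ees_cn": res.ees_cn, "ees_cp": res.ees_cp, "ees_np": res.ees_np,
            "vector_length": res.vector_length, "vector_angle": res.vector_angle,
            "limitation": res.limitation, "flags": ";".join(res.flags),
        })
    return pd.DataFrame(rows, columns=STOICH_COLUMNS)


METRIC_COLUMNS = ["soil_cn", "soil_cp", "soil_np", "ees_cn", "ees_cp", "ees_np",
                  "vector_length", "vector_angle"]


def season_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per season × management group sizes, means and SDs of every metric.

    Rows are ordered lexicographically by (season, management).  Groups
    with no valid values for a metric report n=0 and missing mean/SD; SD
    for n=1 groups is reported missing (a single value has no spread).
    """
    if not {"season", "management"}.issubset(results.columns):
        raise StoichiometryError("season_summary requires season and management columns")
    rows = []
    grouped = results.groupby(["season", "management"], dropna=False)
    for (season, management), grp in sorted(grouped, key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        if len(grp) == 0:  # pragma: no cover - pandas drops empty groups
            logger.info("season_summary: empty group %s/%s omitted", season, management)
            continue
        row: dict[str, object] = {"season": season, "management": management,
                                  "n_samples": len(grp)}
        for metric in METRIC_COLUMNS:
            vals = grp[metric].dropna().astype(float)
            row[f"{metric}_n"] = len(vals)
            row[f"{metric}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        if "limitation" in grp.columns:
            calls = grp["limitation"].dropna()
            row["pct_P_limited"] = (100.0 * (calls == P_LIMITED).mean()
                                    if len(calls) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
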