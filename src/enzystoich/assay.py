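"""Reduction of fluorometric microplate assays to potential enzyme activities.

Soil extracellular enzyme activity (EEA) is assayed by incubating a soil
suspension with a fluorogenic substrate (4-MUB- or AMC-linked) and reading
well fluorescence on a plate reader.  Converting raw fluorescence to
activity (nmol g⁻¹ h⁻¹) requires three corrections:

* an **emission coefficient** (fluorescence per nmol fluorophore) from
  reference-standard wells (standard + water);
* a **quench coefficient** (fraction of standard signal recovered in the
  presence of soil suspension) from quench-standard wells, correcting for
  absorption of light by soil particles;
* subtraction of the **homogenate control** (sample + water) and the
  **substrate control** (substrate + water) signals.

The scheme follows the corrected reduction of German et al. (2011) for the
Saiya-Cork style assay.  Negative net fluorescence is retained and flagged
rather than clamped, so that downstream log-based stoichiometry fails
loudly on bad plates instead of silently digesting zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENZYMES = ("BG", "CBH", "NAG", "LAP", "ACP")

#: fluorophore released per enzyme substrate; AMC pairs with the LAP substrate
FLUOROPHORES = {"BG": "4-MUB", "CBH": "4-MUB", "NAG": "4-MUB", "LAP": "AMC", "ACP": "4-MUB"}

#: replicate wells per role in the reference plate design
DESIGN_REPLICATES = {
    "assay": 6,
    "homog_ctrl": 3,
    "substrate_ctrl": 3,
    "quench_std": 6,
    "ref_std": 6,
}

WELL_ROLES = tuple(DESIGN_REPLICATES)


class AssayError(ValueError):
    """Raised for degenerate plates or invalid assay configuration."""


@dataclass(frozen=True)
class AssayConfig:
    """Physical parameters of the microplate assay.

    Defaults describe the reference protocol: 1 g fresh soil homogenized in
    125 mL deionized water, 200 µL suspension + 50 µL of 200 µM substrate
    per assay well, 50 µL of 10 µM standard (0.5 nmol) per standard well,
    4 h dark incubation at 25 °C, read at 365/450 nm.

    ``moisture_fraction``, if given, converts activities from a fresh-mass
    to a dry-mass basis (dry mass = soil_mass × (1 − moisture_fraction)).
    """

    soil_mass: float = 1.0            # g fresh soil
    suspension_volume: float = 125.0  # mL
    aliquot_volume: float = 0.200     # mL suspension per well
    substrate_volume: float = 0.050   # mL
    substrate_conc: float = 200.0     # µmol L⁻¹
    standard_volume: float = 0.050    # mL
    standard_conc: float = 10.0       # µmol L⁻¹
    incubation_time: float = 4.0      # h
    temperature: float = 25.0         # °C, metadata only
    excitation_nm: float = 365.0      # metadata only
    emission_nm: float = 450.0        # metadata only
    moisture_fraction: float | None = None  # optional dry-mass conversion
    cv_threshold: float = 0.30        # QC: flag assay CV above this

    def __post_init__(self) -> None:
        for name in ("soil_mass", "suspension_volume", "aliquot_volume",
                     "substrate_volume", "substrate_conc", "standard_volume",
                     "standard_conc", "incubation_time"):
            if not getattr(self, name) > 0:
                raise AssayError(f"AssayConfig.{name} must be strictly positive")
        if self.moisture_fraction is not None and not 0 <= self.moisture_fraction < 1:
            raise AssayError("moisture_fraction must lie in [0, 1)")

    @property
    def standard_amount(self) -> float:
        """nmol of standard per standard well (volume × concentration)."""
        # mL × µmol L⁻¹ = nmol
        return self.standard_volume * self.standard_conc

    @property
    def effective_soil_mass(self) -> float:
        if self.moisture_fraction is None:
            return self.soil_mass
        return self.soil_mass * (1.0 - self.moisture_fraction)

    def fluorophore(self, enzyme: str) -> str:
        try:
            return FLUOROPHORES[enzyme]
        except KeyError:
            raise AssayError(f"unknown enzyme {enzyme!r}; expected one of {ENZYMES}") from None


@dataclass(frozen=True)
class PlateBatch:
    """Raw fluorescence readings for one sample × enzyme, grouped by well role."""

    sample_id: str
    enzyme: str
    assay_wells: tuple[float, ...]
    homogenate_control_wells: tuple[float, ...]   # sample + water ("blank")
    substrate_control_wells: tuple[float, ...]    # substrate + water ("negative control")
    quench_standard_wells: tuple[float, ...]      # standard + sample
    reference_standard_wells: tuple[float, ...]   # standard + water

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise AssayError(
                f"{self.sample_id}: unknown enzyme {self.enzyme!r}; expected one of {ENZYMES}")
        for role in ("assay_wells", "homogenate_control_wells", "substrate_control_wells",
                     "quench_standard_wells", "reference_standard_wells"):
            wells = getattr(self, role)
            object.__setattr__(self, role, tuple(float(w) for w in wells))
            wells = getattr(self, role)
            if len(wells) == 0:
                raise AssayError(f"{self.sample_id}/{self.enzyme}: {role} is empty")
            if not all(math.isfinite(w) for w in wells):
                raise AssayError(f"{self.sample_id}/{self.enzyme}: non-finite reading in {role}")

    @property
    def replicate_counts(self) -> dict[str, int]:
        return {
            "assay": len(self.assay_wells),
            "homog_ctrl": len(self.homogenate_control_wells),
            "substrate_ctrl": len(self.substrate_control_wells),
            "quench_std": len(self.quench_standard_wells),
            "ref_std": len(self.reference_standard_wells),
        }


@dataclass
class ActivityEstimate:
    """Reduced activity with all intermediates of the reduction recorded."""

    sample_id: str
    enzyme: str
    activity: float                 # nmol g⁻¹ h⁻¹
    emission_coefficient: float     # fluorescence nmol⁻¹
    quench_coefficient: float       # dimensionless
    net_fluorescence: float         # fluorescence units
    cv: float                       # CV across assay wells
    flags: list[str] = field(default_factory=list)


# --- reduction steps ---------------------------------------------------------

def emission_coefficient(reference_standard_wells, standard_amount: float) -> float:
    """Fluorescence per nmol fluorophore from reference-standard wells."""
    wells = np.asarray(reference_standard_wells, dtype=float)
    if wells.size == 0:
        raise AssayError("reference standard wells empty")
    if not standard_amount > 0:
        raise AssayError("standard_amount must be positive")
    coef = float(wells.mean()) / standard_amount
    if coef <= 0:
        raise AssayError(
            "degenerate plate: non-positive mean reference-standard fluorescence")
    return coef


def quench_coefficient(quench_standard_wells, homogenate_control_wells,
                       reference_standard_wells) -> float:
    """Fraction of standard signal recovered in the presence of soil suspension."""
    q = np.asarray(quench_standard_wells, dtype=float)
    h = np.asarray(homogenate_control_wells, dtype=float)
    r = np.asarray(reference_standard_wells, dtype=float)
    if q.size == 0 or h.size == 0 or r.size == 0:
        raise AssayError("quench computation requires non-empty well groups")
    coef = (float(q.mean()) - float(h.mean())) / float(r.mean())
    if coef <= 0:
        raise AssayError(
            "quench failure: soil suspension absorbed all standard signal "
            f"(quench coefficient {coef:.4g} ≤ 0)")
    return coef


def net_fluorescence(assay_wells, homogenate_control_wells,
                     substrate_control_wells, quench: float) -> float:
    """Blank-, quench- and substrate-corrected assay signal.

    May be negative; callers flag rather than clamp.
    """
    a = np.asarray(assay_wells, dtype=float)
    h = np.asarray(homogenate_control_wells, dtype=float)
    s = np.asarray(substrate_control_wells, dtype=float)
    if a.size == 0 or h.size == 0 or s.size == 0:
        raise AssayError("net fluorescence requires non-empty well groups")
    if not quench > 0:
        raise AssayError("quench coefficient must be positive")
    return (float(a.mean()) - float(h.mean())) / quench - float(s.mean())


def activity_from_plate(batch: PlateBatch, config: AssayConfig | None = None) -> ActivityEstimate:
    """Reduce one plate batch to a potential activity in nmol g⁻¹ h⁻¹.

    activity = net_fluorescence × suspension_volume /
               (emission_coefficient × aliquot_volume × incubation_time × soil_mass)
    """
    config = config or AssayConfig()
    emission = emission_coefficient(batch.reference_standard_wells, config.standard_amount)
    quench = quench_coefficient(batch.quench_standard_wells,
                                batch.homogenate_control_wells,
                                batch.reference_standard_wells)
    net = net_fluorescence(batch.assay_wells, batch.homogenate_control_wells,
                           batch.substrate_control_wells, quench)
    activity = (net * config.suspension_volume) / (
        emission * config.aliquot_volume * config.incubation_time
        * config.effective_soil_mass)

    assay = np.asarray(batch.assay_wells, dtype=float)
    mean = float(assay.mean())
    cv = float(assay.std(ddof=1) / abs(mean)) if assay.size > 1 and mean != 0 else 0.0

    flags = validate_plate(batch, config, _quench=quench, _net=net, _cv=cv)
    if net < 0:
        flags = sorted(set(flags) | {"below-blank"})
    return ActivityEstimate(
        sample_id=batch.sample_id, enzyme=batch.enzyme, activity=activity,
        emission_coefficient=emission, quench_coefficient=quench,
        net_fluorescence=net, cv=cv, flags=list(flags))


def validate_plate(batch: PlateBatch, config: AssayConfig | None = None, *,
                   _quench: float | None = None, _net: float | None = None,
                   _cv: float | None = None) -> list[str]:
    """Report-only QC: replicate-count deviations, high CV, negative net
    fluorescence, quench outside (0.2, 1.2]."""
    config = config or AssayConfig()
    flags: list[str] = []
    for role, expected in DESIGN_REPLICATES.items():
        n = batch.replicate_counts[role]
        if n != expected:
            flags.append(f"replicate-count:{role}={n}(expected {expected})")
    try:
        quench = _quench if _quench is not None else quench_coefficient(
            batch.quench_standard_wells, batch.homogenate_control_wells,
            batch.reference_standard_wells)
        if not 0.2 < quench <= 1.2:
            flags.append(f"quench-out-of-range:{quench:.4g}")
        if _net is not None:
            net = _net
        else:
            net = net_fluorescence(batch.assay_wells, batch.homogenate_control_wells,
                                   batch.substrate_control_wells, quench)
        if net < 0:
            flags.append("negative-net-fluorescence")
    except AssayError as exc:
        flags.append(f"reduction-error:{exc}")
    if _cv is None:
        assay = np.asarray(batch.assay_wells, dtype=float)
        mean = float(assay.mean())
        _cv = float(assay.std(ddof=1) / abs(mean)) if assay.size > 1 and mean != 0 else 0.0
    if _cv > config.cv_threshold:
        flags.append(f"high-cv:{_cv:.3g}")
    return flags


def reduce_plates(batches, config: AssayConfig | None = None) -> pd.DataFrame:
    """Reduce a collection of plate batches to a per-sample activity table.

    Returns one row per sample with columns ``bg, cbh, nag, lap, acp`` plus
    per-enzyme ``cv_<enz>`` and a semicolon-joined ``flags`` column.  Samples
    missing an enzyme keep NaN in that column and get a ``missing:<ENZ>``
    flag; duplicate sample × enzyme batches are a hard error.
    """
    config = config or AssayConfig()
    estimates: dict[str, dict[str, ActivityEstimate]] = {}
    order: list[str] = []
    for batch in batches:
        per_sample = estimates.setdefault(batch.sample_id, {})
        if batch.sample_id not in order:
            order.append(batch.sample_id)
        if batch.enzyme in per_sample:
            raise AssayError(
                f"duplicate plate batch for sample {batch.sample_id!r} "
                f"enzyme {batch.enzyme}")
        per_sample[batch.enzyme] = activity_from_plate(batch, config)

    rows = []
    for sample_id in order:
        per_sample = estimates[sample_id]
        row: dict[str, object] = {"sample_id": sample_id}
        flags: list[str] = []
        for enzyme in ENZYMES:
            col = enzyme.lower()
            est = per_sample.get(enzyme)
            if est is None:
                row[col] = np.nan
                row[f"cv_{col}"] = np.nan
                flags.append(f"missing:{enzyme}")
            else:
                row[col] = est.activity
                row[f"cv_{col}"] = est.cv
                flags.extend(f"{enzyme}:{f}" for f in est.flags)
        row["flags"] = ";".join(flags)
        rows.append(row)
    columns = (["sample_id"] + [e.lower() for e in ENZYMES]
               + [f"cv_{e.lower()}" for e in ENZYMES] + ["flags"])
    return pd.DataFrame(rows, columns=columns)


# --- plate CSV I/O -----------------------------------------------------------

PLATE_CSV_COLUMNS = ["plate_id", "sample_id", "enzyme", "well_role", "replicate",
                     "fluorescence"]

_ROLE_TO_FIELD = {
    "assay": "assay_wells",
    "homog_ctrl": "homogenate_control_wells",
    "substrate_ctrl": "substrate_control_wells",
    "quench_std": "quench_standard_wells",
    "ref_std": "reference_standard_wells",
}


def read_plate_csv(path) -> list[PlateBatch]:
    """Read the long-format plate CSV into PlateBatch objects.

    Expected columns: plate_id, sample_id, enzyme {BG,CBH,NAG,LAP,ACP},
    well_role {assay,homog_ctrl,substrate_ctrl,quench_std,ref_std},
    replicate, fluorescence.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise AssayError(f"plate CSV missing columns: {missing}")
    bad_roles = set(df["well_role"]) - set(_ROLE_TO_FIELD)
    if bad_roles:
        raise AssayError(f"plate CSV has unknown well roles: {sorted(bad_roles)}")
    batches = []
    for (sample_id, enzyme), grp in df.groupby(["sample_id", "enzyme"], sort=False):
        kwargs = {}
        for role, fname in _ROLE_TO_FIELD.items():
            sub = grp[grp["well_role"] == role].sort_values("replicate")
            kwargs[fname] = tuple(sub["fluorescence"].astype(float))
        batches.append(PlateBatch(sample_id=str(sample_id), enzyme=str(enzyme), **kwargs))
    return batches


def plates_to_frame(batches) -> pd.DataFrame:
    """Inverse of :func:`read_plate_csv`: long-format table of well readings."""
    records = []
    for batch in batches:
        for role, fname in _ROLE_TO_FIELD.items():
            for i, value in enumerate(getattr(batch, fname), start=1):
                records.append({
                    "plate_id": f"{batch.sample_id}:{batch.enzyme}",
                    "sample_id": batch.sample_id, "enzyme": batch.enzyme,
                    "well_role": role, "replicate": i, "fluorescence": value,
                })
    return pd.DataFrame(records, columns=PLATE_CSV_COLUMNS)
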