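"""Techno-economic model of a mosquito mass-rearing and release facility.

The model compares four sex-sorting systems for sterile-male programmes:

* ``size_manual`` — manual glass-plate sorting of pupae by size dimorphism;
* ``size_auto``   — automated (robotic) pupal size sorting;
* ``gss``         — a single genetic sexing strain, fluorescence-sorted as
  first-instar (L1) larvae on a COPAS;
* ``gss_cs``      — two sexing strains combined in a crossing scheme, with
  non-transgenic male offspring fluorescence-sorted at L1.

Given a weekly male release target, the model back-calculates the weekly egg
demand through sorting recovery, survival, hatch and fecundity; builds the
colony structure of each system (a release line; self-sustaining production
colonies for the size systems; for the sexing strains, rearing colonies
whose replacement adults hatch from dedicated *filter colonies* that are
double-sorted every generation — COPAS at L1 plus a pupal re-check — to
purge recombinant contaminants; for the crossing scheme, two such
filter/rearing chains plus a layer of cross cages).  Sorting at L1 lets
female larvae exit after one day instead of being reared to pupation, which
is the driver of the sexing strains' savings.

Standing stocks use the steady-state reading: weekly stage throughput ×
stage residence time in weeks.  Costs are computed in euros and converted to
US dollars at a configured rate; percent comparisons between systems are
independent of that rate.  Equipment and staff are provisioned in integer
units by ceiling of demand over capacity.  The model evaluates scenarios; it
does not optimize.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "BiologyParams",
    "EquipmentSpec",
    "CostParams",
    "SexingSystem",
    "ParamBundle",
    "FacilityPlan",
    "SystemComparison",
    "COMPARISON_METRICS",
    "default_config_path",
    "load_params",
    "save_params",
    "plan_facility",
    "compare_systems",
]

DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class BiologyParams:
    """Colony biology and husbandry densities (durations in days)."""

    eggs_per_female_per_week: float
    hatch_rate: float
    survival_l1_to_pupa: float
    survival_pupa_to_adult: float
    sex_ratio: float
    duration_egg_days: float
    duration_l1_days: float
    duration_l2_l4_days: float
    duration_pupa_days: float
    duration_prerelease_days: float
    adult_colony_lifespan_weeks: float
    larvae_per_tray: float
    trays_per_m2: float
    adults_per_cage: float
    cages_per_m2: float
    area_overhead_factor: float

    def __post_init__(self):
        for name in ("hatch_rate", "survival_l1_to_pupa", "survival_pupa_to_adult", "sex_ratio"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for f in dc_fields(self):
            if f.name.startswith("duration") and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass(frozen=True)
class EquipmentSpec:
    """One catalogue item; capacity is per week (throughput items) or a
    standing capacity (racks, cages)."""

    unit_cost: float
    lifespan_years: float
    weekly_capacity: float | None = None
    standing_capacity: float | None = None

    def __post_init__(self):
        if self.unit_cost < 0 or self.lifespan_years <= 0:
            raise ValueError("equipment cost must be >= 0 and lifespan > 0")
        if (self.weekly_capacity is None) == (self.standing_capacity is None):
            raise ValueError("give exactly one of weekly_capacity / standing_capacity")

    @property
    def capacity(self) -> float:
        return self.weekly_capacity if self.weekly_capacity is not None else self.standing_capacity


@dataclass(frozen=True)
class CostParams:
    """Cost catalogue (euros) and staffing rates."""

    eur_to_usd: float
    construction_cost_per_m2: float
    building_lifespan_years: float
    operating_weeks_per_year: float
    diet_cost_per_larva: float
    l1_diet_fraction: float
    adult_food_cost_per_adult_week: float
    consumable_cost_per_released_male: float
    equipment: Mapping[str, EquipmentSpec]
    staff: Mapping[str, float]

    def __post_init__(self):
        for name in (
            "eur_to_usd",
            "construction_cost_per_m2",
            "diet_cost_per_larva",
            "adult_food_cost_per_adult_week",
            "consumable_cost_per_released_male",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.building_lifespan_years <= 0:
            raise ValueError("building_lifespan_years must be > 0")


_SYSTEM_COLONY_STRUCTURE = {
    # id: (n_filter_colonies, n_rearing_colonies)
    "size_manual": (0, 1),
    "size_auto": (0, 1),
    "gss": (1, 1),
    "gss_cs": (2, 2),
}


@dataclass(frozen=True)
class SexingSystem:
    """One sex-sorting system and its colony structure."""

    id: str
    sorting_stage: str  # "pupa" or "l1"
    male_recovery: float
    female_contamination: float
    sorter: str  # equipment id of the sorting device
    manual_sort: bool = False
    n_filter_colonies: int = 0
    n_rearing_colonies: int = 1
    filter_copas_recovery: float = 0.696
    filter_pupal_recovery: float = 0.9

    def __post_init__(self):
        if self.sorting_stage not in ("pupa", "l1"):
            raise ValueError("sorting_stage must be 'pupa' or 'l1'")
        if not 0.0 < self.male_recovery <= 1.0:
            raise ValueError("male_recovery must be in (0, 1]")
        if not 0.0 <= self.female_contamination <= 1.0:
            raise ValueError("female_contamination must be in [0, 1]")
        expected = _SYSTEM_COLONY_STRUCTURE.get(self.id)
        if expected is not None and expected != (self.n_filter_colonies, self.n_rearing_colonies):
            raise ValueError(
                f"system {self.id!r} requires {expected[0]} filter and "
                f"{expected[1]} rearing colonies"
            )


@dataclass(frozen=True)
class ParamBundle:
    biology: BiologyParams
    costs: CostParams
    systems: Mapping[str, SexingSystem]


def default_config_path() -> Path:
    return Path(resources.files("aedes_gss") / "data" / "facility_defaults.yaml")


def _require(section: Mapping, keys: Iterable[str], prefix: str, errors: list[str]) -> None:
    for k in keys:
        if k not in section:
            errors.append(f"missing key {prefix}{k}")


def load_params(config: str | Path | Mapping | None = None) -> ParamBundle:
    """Load and validate a parameter bundle from YAML/JSON or a mapping.

    ``None`` loads the bundled default configuration.  All schema violations
    are collected and reported together.
    """
    if config is None:
        config = default_config_path()
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        raw = json.loads(text) if str(config).endswith(".json") else yaml.safe_load(text)
    else:
        raw = dict(config)

    errors: list[str] = []
    for section in ("biology", "costs", "systems"):
        if section not in raw:
            errors.append(f"missing section {section}")
    if errors:
        raise ValueError("invalid facility config: " + "; ".join(errors))

    bio_keys = [f.name for f in dc_fields(BiologyParams)]
    _require(raw["biology"], bio_keys, "biology.", errors)
    cost_keys = [f.name for f in dc_fields(CostParams)]
    _require(raw["costs"], cost_keys, "costs.", errors)
    if "equipment" in raw["costs"]:
        for eq_id, spec in raw["costs"]["equipment"].items():
            _require(spec, ("unit_cost", "lifespan_years"), f"costs.equipment.{eq_id}.", errors)
    sys_keys = ("sorting_stage", "male_recovery", "female_contamination", "sorter")
    for sid, spec in raw.get("systems", {}).items():
        _require(spec, sys_keys, f"systems.{sid}.", errors)
    if errors:
        raise ValueError("invalid facility config: " + "; ".join(errors))

    biology = BiologyParams(**{k: raw["biology"][k] for k in bio_keys})
    equipment = {
        eq_id: EquipmentSpec(**spec) for eq_id, spec in raw["costs"]["equipment"].items()
    }
    cost_kwargs = {k: raw["costs"][k] for k in cost_keys if k not in ("equipment", "staff")}
    costs = CostParams(equipment=equipment, staff=dict(raw["costs"]["staff"]), **cost_kwargs)
    systems = {sid: SexingSystem(id=sid, **spec) for sid, spec in raw["systems"].items()}
    for system in systems.values():
        if system.sorter not in costs.equipment:
            raise ValueError(f"system {system.id!r} references unknown sorter {system.sorter!r}")
    return ParamBundle(biology=biology, costs=costs, systems=systems)


def save_params(bundle: ParamBundle, path: str | Path) -> None:
    """Write a parameter bundle back to YAML/JSON (round-trips with load)."""
    raw = {
        "biology": {f.name: getattr(bundle.biology, f.name) for f in dc_fields(BiologyParams)},
        "costs": {
            **{
                f.name: getattr(bundle.costs, f.name)
                for f in dc_fields(CostParams)
                if f.name not in ("equipment", "staff")
            },
            "equipment": {
                eq_id: {
                    k: v
                    for k, v in {
                        "unit_cost": eq.unit_cost,
                        "lifespan_years": eq.lifespan_years,
                        "weekly_capacity": eq.weekly_capacity,
                        "standing_capacity": eq.standing_capacity,
                    }.items()
                    if v is not None
                }
                for eq_id, eq in bundle.costs.equipment.items()
            },
            "staff": dict(bundle.costs.staff),
        },
        "systems": {
            sid: {
                f.name: getattr(s, f.name)
                for f in dc_fields(SexingSystem)
                if f.name != "id"
            }
            for sid, s in bundle.systems.items()
        },
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(raw, indent=2))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=True))


# ---------------------------------------------------------------------------
# Weekly steady-state flows


@dataclass
class _Stream:
    """One weekly rearing cohort pipeline.

    ``l1`` larvae enter per week; ``kept`` continue past L1 (for L1-sorted
    streams the rest exit after one day); ``pupae`` enter the pupal stage per
    week; sorter loads are larvae/pupae passing through devices per week.
    """

    name: str
    l1: float
    kept: float
    pupae: float
    copas_load: float = 0.0
    pupal_sort_load: float = 0.0
    manual_pupal_load: float = 0.0


@dataclass
class _Colony:
    name: str
    females: float
    eggs_out: float

    @property
    def adults(self) -> float:
        return 2.0 * self.females  # cages kept at 1:1


def _self_sustaining_females(
    eggs_out: float, bio: BiologyParams, repl_efficiency: float
) -> float:
    """Females of a colony that produces ``eggs_out`` per week for others and
    also rears its own weekly replacements at the given egg→adult efficiency.

    Solves F·epf = eggs_out + (2F/L)/e; the chain diverges if per-female
    output cannot cover replacement demand.
    """
    epf = bio.eggs_per_female_per_week
    L = bio.adult_colony_lifespan_weeks
    denom = epf - 2.0 / (L * repl_efficiency)
    if denom <= 0:
        raise ValueError(
            "divergent colony demand: fecundity cannot sustain replacement rearing"
        )
    return eggs_out / denom


@dataclass(frozen=True)
class FacilityPlan:
    """Steady-state weekly plan for one system at one release target.

    Costs are in US dollars (converted from the euro-denominated catalogue at
    ``fx_rate``); stocks are individuals present at any time.
    """

    system_id: str
    release_target: float
    eggs_per_week: float
    l1_per_week: float
    full_reared_larvae_per_week: float
    pupae_per_week: float
    larvae_at_any_time: float
    pupae_at_any_time: float
    adults_at_any_time: float
    area_m2: float
    construction_cost: float
    construction_cost_yearly: float
    equipment_cost_yearly: float
    diet_consumables_yearly: float
    total_yearly: float
    staff: int
    equipment_units: Mapping[str, int]
    colonies: Mapping[str, float]  # colony name -> adults standing
    fx_rate: float
    currency: str = "USD"

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        d["equipment_units"] = dict(self.equipment_units)
        d["colonies"] = dict(self.colonies)
        return d


def _build_streams_and_colonies(
    system: SexingSystem, release_target: float, bio: BiologyParams
) -> tuple[list[_Stream], list[_Colony]]:
    T = float(release_target)
    s_lp = bio.survival_l1_to_pupa
    s_pa = bio.survival_pupa_to_adult
    h = bio.hatch_rate
    sr = bio.sex_ratio
    epf = bio.eggs_per_female_per_week
    L = bio.adult_colony_lifespan_weeks
    e_unsorted = h * s_lp * s_pa
    e_filter = h * system.filter_copas_recovery * s_lp * system.filter_pupal_recovery * s_pa

    streams: list[_Stream] = []
    colonies: list[_Colony] = []

    # --- release line -------------------------------------------------------
    if system.sorting_stage == "l1":
        kept = T / (s_pa * s_lp)  # male L1 retained at the sorter
        l1 = kept / (system.male_recovery * sr)
        release = _Stream(
            "release_line", l1=l1, kept=kept, pupae=kept * s_lp, copas_load=l1
        )
    else:
        male_pupae_kept = T / s_pa
        pupae_presented = male_pupae_kept / (system.male_recovery * sr)
        l1 = pupae_presented / s_lp
        release = _Stream(
            "release_line",
            l1=l1,
            kept=l1,
            pupae=pupae_presented,
            pupal_sort_load=pupae_presented,
            manual_pupal_load=pupae_presented if system.manual_sort else 0.0,
        )
    streams.append(release)
    eggs_release = release.l1 / h

    def unsorted_replacement_stream(name: str, adults_needed: float) -> _Stream:
        l1_r = adults_needed / (s_lp * s_pa)
        return _Stream(name, l1=l1_r, kept=l1_r, pupae=l1_r * s_lp)

    def filter_replacement_stream(name: str, adults_needed: float) -> _Stream:
        # L1 COPAS pass -> rear survivors -> pupal re-check -> emergence.
        l1_f = adults_needed / (
            system.filter_copas_recovery * s_lp * system.filter_pupal_recovery * s_pa
        )
        kept_f = l1_f * system.filter_copas_recovery
        pupae_f = kept_f * s_lp
        return _Stream(
            name,
            l1=l1_f,
            kept=kept_f,
            pupae=pupae_f,
            copas_load=l1_f,
            manual_pupal_load=pupae_f,  # pupal re-check is a manual screen
        )

    if system.n_filter_colonies == 0:
        # Size-sorting systems: one self-sustaining production colony.
        females = _self_sustaining_females(eggs_release, bio, e_unsorted)
        colony = _Colony("production_colony", females=females, eggs_out=eggs_release)
        colonies.append(colony)
        streams.append(
            unsorted_replacement_stream("production_colony_replacement", 2.0 * females / L)
        )
    elif system.id == "gss" or (
        system.n_filter_colonies == 1 and system.n_rearing_colonies == 1
    ):
        # Single sexing strain: rearing colony fed by one filter colony.
        f_rear = eggs_release / epf
        colonies.append(_Colony("rearing_colony", females=f_rear, eggs_out=eggs_release))
        repl = unsorted_replacement_stream("rearing_colony_replacement", 2.0 * f_rear / L)
        streams.append(repl)
        eggs_filter_out = repl.l1 / h
        f_filt = _self_sustaining_females(eggs_filter_out, bio, e_filter)
        colonies.append(_Colony("filter_colony", females=f_filt, eggs_out=eggs_filter_out))
        streams.append(
            filter_replacement_stream("filter_colony_replacement", 2.0 * f_filt / L)
        )
    else:
        # Crossing scheme: cross cages fed by two rearing colonies (sorted
        # parents), each backed by its own filter colony.
        f_cross = eggs_release / epf
        colonies.append(_Colony("cross_cages", females=f_cross, eggs_out=eggs_release))
        adults_cross_repl = 2.0 * f_cross / L
        for strain in ("M_strain", "m_strain"):
            # Half of the cross replacements come from each side, sorted at L1
            # for the wanted class (one sex at the Mendelian 1:2 within sex).
            kept_parents = (adults_cross_repl / 2.0) / (s_lp * s_pa)
            l1_parents = kept_parents / (system.male_recovery * 0.5)
            streams.append(
                _Stream(
                    f"{strain}_cross_parents",
                    l1=l1_parents,
                    kept=kept_parents,
                    pupae=kept_parents * s_lp,
                    copas_load=l1_parents,
                )
            )
            eggs_rc = l1_parents / h
            f_rc = eggs_rc / epf
            colonies.append(_Colony(f"{strain}_rearing_colony", females=f_rc, eggs_out=eggs_rc))
            repl = unsorted_replacement_stream(
                f"{strain}_rearing_colony_replacement", 2.0 * f_rc / L
            )
            streams.append(repl)
            eggs_fc = repl.l1 / h
            f_fc = _self_sustaining_females(eggs_fc, bio, e_filter)
            colonies.append(_Colony(f"{strain}_filter_colony", females=f_fc, eggs_out=eggs_fc))
            streams.append(
                filter_replacement_stream(f"{strain}_filter_colony_replacement", 2.0 * f_fc / L)
            )
    return streams, colonies


def plan_facility(
    system: SexingSystem,
    release_target: float,
    bio: BiologyParams,
    cost: CostParams,
) -> FacilityPlan:
    """Size and cost one facility for a weekly male release target."""
    if release_target <= 0:
        raise ValueError("release_target must be positive")
    T = float(release_target)
    streams, colonies = _build_streams_and_colonies(system, T, bio)

    d_l1 = bio.duration_l1_days / DAYS_PER_WEEK
    d_l24 = bio.duration_l2_l4_days / DAYS_PER_WEEK
    d_pup = bio.duration_pupa_days / DAYS_PER_WEEK
    d_pre = bio.duration_prerelease_days / DAYS_PER_WEEK

    l1_week = sum(s.l1 for s in streams)
    full_week = sum(s.kept for s in streams)
    pupae_week = sum(s.pupae for s in streams)
    eggs_week = l1_week / bio.hatch_rate

    larvae_standing = sum(s.l1 * d_l1 + s.kept * d_l24 for s in streams)
    pupae_standing = sum(s.pupae * d_pup for s in streams)
    colony_adults = sum(c.adults for c in colonies)
    adults_standing = colony_adults + T * d_pre

    larvae_area = (larvae_standing + pupae_standing) / (bio.larvae_per_tray * bio.trays_per_m2)
    adult_area = adults_standing / (bio.adults_per_cage * bio.cages_per_m2)
    area = (larvae_area + adult_area) * bio.area_overhead_factor

    # --- equipment (integer units by ceiling of demand over capacity) -------
    units: dict[str, int] = {}

    def provision(eq_id: str, demand: float) -> None:
        if demand <= 0:
            return
        units[eq_id] = units.get(eq_id, 0) + math.ceil(
            demand / cost.equipment[eq_id].capacity
        )

    provision("copas", sum(s.copas_load for s in streams))
    provision(system.sorter if system.sorting_stage == "pupa" else "glass_plate_station",
              sum(s.pupal_sort_load for s in streams))
    # Filter-colony pupal re-checks run on manual glass-plate stations.
    manual_recheck = sum(s.manual_pupal_load for s in streams) - sum(
        s.manual_pupal_load for s in streams if s.name == "release_line"
    )
    provision("glass_plate_station", manual_recheck)
    provision("larval_rack", larvae_standing + pupae_standing)
    provision("adult_cage", adults_standing)

    equipment_yearly_eur = sum(
        n * cost.equipment[eq_id].unit_cost / cost.equipment[eq_id].lifespan_years
        for eq_id, n in units.items()
    )

    # --- variable costs ------------------------------------------------------
    l1_only = l1_week - full_week
    diet_weekly = (
        full_week * cost.diet_cost_per_larva
        + l1_only * cost.diet_cost_per_larva * cost.l1_diet_fraction
        + adults_standing * cost.adult_food_cost_per_adult_week
        + T * cost.consumable_cost_per_released_male
    )
    diet_yearly_eur = diet_weekly * cost.operating_weeks_per_year

    construction_eur = area * cost.construction_cost_per_m2

    # --- staff ---------------------------------------------------------------
    rates = cost.staff
    manual_sort_load = sum(s.manual_pupal_load for s in streams)
    sorter_units = units.get("copas", 0) + (
        units.get("pupal_sorter_auto", 0) if system.sorting_stage == "pupa" else 0
    )
    staff_f = (
        l1_week / rates["larvae_reared_per_person_week"]
        + adults_standing / rates["adults_kept_per_person_week"]
        + manual_sort_load / rates["pupae_hand_sorted_per_person_week"]
        + T / rates["males_released_per_person_week"]
        + sorter_units * rates["operators_per_sorter_unit"]
    )
    staff = math.ceil(staff_f)

    fx = cost.eur_to_usd
    construction = construction_eur * fx
    construction_yearly = construction / cost.building_lifespan_years
    equipment_yearly = equipment_yearly_eur * fx
    diet_yearly = diet_yearly_eur * fx

    return FacilityPlan(
        system_id=system.id,
        release_target=T,
        eggs_per_week=eggs_week,
        l1_per_week=l1_week,
        full_reared_larvae_per_week=full_week,
        pupae_per_week=pupae_week,
        larvae_at_any_time=larvae_standing,
        pupae_at_any_time=pupae_standing,
        adults_at_any_time=adults_standing,
        area_m2=area,
        construction_cost=construction,
        construction_cost_yearly=construction_yearly,
        equipment_cost_yearly=equipment_yearly,
        diet_consumables_yearly=diet_yearly,
        total_yearly=construction_yearly + equipment_yearly + diet_yearly,
        staff=staff,
        equipment_units=units,
        colonies={c.name: c.adults for c in colonies},
        fx_rate=fx,
    )


COMPARISON_METRICS = (
    "larvae_at_any_time",
    "adults_at_any_time",
    "area_m2",
    "construction_cost",
    "equipment_cost_yearly",
    "diet_consumables_yearly",
    "total_yearly",
    "staff",
)


@dataclass(frozen=True)
class SystemComparison:
    """Per-metric percent differences of each system against a baseline."""

    baseline: str
    table: pd.DataFrame  # columns: system, target, metric, value, pct_vs_baseline

    def pct(self, system: str, metric: str, target: float) -> float:
        t = self.table
        row = t[(t.system == system) & (t.metric == metric) & (t.target == target)]
        if row.empty:
            raise KeyError(f"no comparison for ({system}, {metric}, {target})")
        return float(row.pct_vs_baseline.iloc[0])


def compare_systems(
    systems: Sequence[SexingSystem],
    targets: Sequence[float],
    bio: BiologyParams,
    cost: CostParams,
    baseline: str = "size_manual",
) -> SystemComparison:
    """Compare facility metrics across systems and release targets.

    Percent differences are 100·(value/baseline − 1); a system compared to
    itself is 0% on every metric.
    """
    if len(systems) < 2:
        raise ValueError("need at least two systems to compare")
    ids = [s.id for s in systems]
    if baseline not in ids:
        raise ValueError(f"baseline {baseline!r} not among systems {ids}")
    rows = []
    for target in targets:
        plans = {s.id: plan_facility(s, target, bio, cost) for s in systems}
        base = plans[baseline]
        for sid, plan in plans.items():
            for metric in COMPARISON_METRICS:
                v = float(getattr(plan, metric))
                b = float(getattr(base, metric))
                pct = 0.0 if sid == baseline else 100.0 * (v / b - 1.0)
                rows.append(
                    {
                        "system": sid,
                        "target": float(target),
                        "metric": metric,
                        "value": v,
                        "pct_vs_baseline": pct,
                    }
                )
    return SystemComparison(baseline=baseline, table=pd.DataFrame(rows))
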