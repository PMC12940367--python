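"""Synthetic whole-blood cytometry generator.

Because no event-level BAT data are publicly deposited, every
downstream stage of this package is exercised against seeded synthetic
samples that plant the statistical structure the analysis assumes:

* an erythrolyzed whole-blood event mixture in which basophils are a
  rare SSC-low / FceRIa-high population next to other leukocytes and
  debris;
* allergen dose-dependent CD63 upregulation in allergic patients,
  modelled as a two-component CD63 mixture on basophils whose activated
  weight follows a Hill curve in the stimulation concentration;
* baseline-only activation in tolerant patients, non-responder
  phenotypes (IgE pathway silent, fMLP pathway intact);
* OFC-status-dependent serum sIgE distributions (log-normal per marker
  and status), with omega-5 gliadin (Tri a 19) planted as a
  near-perfect separator while the extract sIgEs overlap;
* CD32 downregulation on basophils after allergic OFC reactions.

Intensities are generated as Gaussians on log10 scale and
exponentiated; no spillover/compensation or instrument artifacts are
simulated.  Every sample carries a ground-truth sidecar with planted
population and activation labels so gate- and parameter-recovery can be
scored exactly.  Seeds propagate hierarchically (cohort seed ->
per-patient -> per-sample) and each per-sample seed is recorded in the
manifest, so any single sample is reproducible in isolation; identical
seeds give bit-identical output.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .events import (
    CD32,
    CD63,
    FCERI,
    MARKERS,
    SSC,
    EventTable,
    PatientRecord,
    SampleRecord,
    StimulationCondition,
)

WHEAT_ALLERGENS = frozenset({"gluten", "gliadin", "wheat"})

#: Final stimulation concentrations of the default allergen panel (ug/mL).
DEFAULT_CONCENTRATIONS = {"gluten": 400.0, "gliadin": 300.0, "wheat": 50.0,
                          "timothy_grass": 1.0}


def default_condition_panel() -> list:
    """Negative control, the four-allergen panel, and both positive controls."""
    panel = [StimulationCondition("negative_control")]
    panel += [StimulationCondition("allergen", allergen=a, concentration=c)
              for a, c in DEFAULT_CONCENTRATIONS.items()]
    panel += [StimulationCondition("anti_IgE"), StimulationCondition("fMLP")]
    return panel


@dataclass(frozen=True)
class PopulationSpec:
    """One component of the whole-blood event mixture.

    ``channels`` maps each marker to a ``(location, scale)`` pair on
    log10 fluorescence scale.  ``correlation``, if given, is a common
    pairwise correlation applied between all channels.
    """

    name: str
    fraction: float
    channels: dict
    correlation: float | None = None

    def __post_init__(self):
        if self.name not in ("basophil", "other_leukocyte", "debris"):
            raise ValueError(f"unknown population {self.name!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("population fraction must be in [0, 1]")
        for m in MARKERS:
            if m not in self.channels:
                raise ValueError(f"population {self.name}: missing channel {m}")
            loc, scale = self.channels[m]
            if scale <= 0:
                raise ValueError(f"population {self.name}: scale for {m} must be > 0")
        if self.correlation is not None and not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")


def default_populations(basophil_fraction: float = 0.005) -> list:
    """Default erythrolyzed whole-blood mixture geometry (log10 scale).

    Basophils sit SSC-low and ~30x above the leukocyte FceRIa mode, well
    clear of the density valley between the debris and leukocyte SSC
    modes, so the valley gating strategy recovers them with high F1.
    """
    rest = 1.0 - basophil_fraction
    return [
        PopulationSpec("basophil", basophil_fraction, {
            SSC: (1.88, 0.08), FCERI: (2.50, 0.12),
            CD63: (1.00, 0.15), CD32: (2.30, 0.15)}),
        PopulationSpec("other_leukocyte", rest * 0.70, {
            SSC: (2.50, 0.15), FCERI: (1.00, 0.15),
            CD63: (0.90, 0.20), CD32: (1.60, 0.25)}),
        PopulationSpec("debris", rest * 0.30, {
            SSC: (1.70, 0.18), FCERI: (0.85, 0.22),
            CD63: (0.80, 0.25), CD32: (1.00, 0.30)}),
    ]


@dataclass(frozen=True)
class ResponseModel:
    """Basophil CD63 response of one patient.

    The activated-component weight of the basophil CD63 mixture is
    ``f_base`` for the negative control and follows a Hill curve

        w(d) = f_base + (f_max - f_base) * d**h / (ec50**h + d**h)

    for allergen stimulations on responsive pathways; anti-IgE and fMLP
    force the saturating weight ``f_max`` on their respective pathways.
    Activated basophils have their CD63 location shifted by
    ``cd63_shift`` on log10 scale.
    """

    f_base: float = 0.01
    f_max: float = 0.6
    ec50: float = 40.0  # ug/mL
    hill: float = 1.0
    cd63_shift: float = 1.2
    responds_allergen: bool = True
    responds_anti_ige: bool = True
    responds_fmlp: bool = True

    def __post_init__(self):
        if not 0.0 <= self.f_base <= 1.0:
            raise ValueError("f_base must be in [0, 1]")
        if not self.f_base < self.f_max <= 1.0:
            raise ValueError("f_max must be in (f_base, 1]")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be > 0")

    def activation_weight(self, condition: StimulationCondition) -> float:
        """Planted activated fraction for one stimulation condition."""
        k = condition.kind
        if k == "negative_control":
            return self.f_base
        if k == "allergen":
            if not self.responds_allergen:
                return self.f_base
            d = float(condition.concentration)
            frac = d ** self.hill / (self.ec50 ** self.hill + d ** self.hill)
            return self.f_base + (self.f_max - self.f_base) * frac
        if k == "anti_IgE":
            return self.f_max if self.responds_anti_ige else self.f_base
        if k == "fMLP":
            return self.f_max if self.responds_fmlp else self.f_base
        raise ValueError(f"unknown condition kind {k!r}")


@dataclass(frozen=True)
class CD32MixtureModel:
    """Two-component CD32 mixture on basophils (log10 locations)."""

    loc_positive: float = 2.30
    loc_negative: float = 1.30
    scale: float = 0.15


@dataclass(frozen=True)
class CD32KineticsSpec:
    """Planted CD32+ basophil kinetics over an OFC time series."""

    baseline_fraction: float = 0.7
    downregulation_factor: float = 0.6  # allergic post-reaction multiplier
    tolerant_drift_factor: float = 1.0
    noise_sd: float = 0.02  # per-timepoint additive noise on the fraction

    def __post_init__(self):
        if not 0.0 < self.baseline_fraction <= 1.0:
            raise ValueError("baseline fraction must be in (0, 1]")
        if not 0.0 < self.downregulation_factor < 1.0:
            raise ValueError("downregulation factor must be in (0, 1)")
        if self.tolerant_drift_factor <= 0:
            raise ValueError("drift factor must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise scale must be >= 0")


def _default_sige_params() -> dict:
    # marker -> status -> (log10 location, log10 scale), values in kU/L.
    return {
        "tri_a_19": {"allergic": (1.0, 0.5), "tolerant": (-1.6, 0.4)},
        "wheat_f4": {"allergic": (0.9, 0.8), "tolerant": (0.3, 0.8)},
        "gluten_f79": {"allergic": (0.7, 0.8), "tolerant": (0.2, 0.8)},
    }


@dataclass
class CohortSpec:
    """Study-cohort generator parameters.

    The child preset mirrors the study design: 14 allergic and 11
    tolerant children with one planted IgE non-responder; the adult
    preset plants 18/9 with one non-responder.  Tolerant patients may
    carry elevated extract sIgE (sensitized-but-tolerant); marker
    distributions are configurable so Tri a 19 separates nearly
    perfectly by default while the extract markers overlap.
    """

    n_allergic: int
    n_tolerant: int
    cohort: str = "child"
    non_responder_count: int = 0
    sige_params: dict = field(default_factory=_default_sige_params)
    f_max_range: tuple = (0.25, 0.75)
    ec50_log10_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_allergic < 0 or self.n_tolerant < 0:
            raise ValueError("patient counts must be >= 0")
        if not 0 <= self.non_responder_count <= self.n_allergic:
            raise ValueError("non_responder_count must be in [0, n_allergic]")
        if self.cohort not in ("child", "adult"):
            raise ValueError(f"unknown cohort {self.cohort!r}")


CHILD_COHORT = CohortSpec(n_allergic=14, n_tolerant=11, cohort="child",
                          non_responder_count=1)
ADULT_COHORT = CohortSpec(n_allergic=18, n_tolerant=9, cohort="adult",
                          non_responder_count=1)


# ---------------------------------------------------------------------------
# event-level simulation
# ---------------------------------------------------------------------------

def simulate_events(
    populations: list,
    response: ResponseModel,
    condition: StimulationCondition,
    n_events: int,
    seed: int,
    *,
    cd32_model: CD32MixtureModel | None = None,
    cd32_positive_weight: float | None = None,
) -> EventTable:
    """Draw one stimulated sample from the population mixture.

    Basophil CD63 is a two-component mixture whose activated weight
    comes from ``response.activation_weight(condition)``.  If
    ``cd32_positive_weight`` is given, basophil CD32 is drawn from the
    two-component ``cd32_model`` instead of the population location
    (used for OFC time series).  Ground-truth labels are retained in
    ``table.truth``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    fractions = np.array([p.fraction for p in populations], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {fractions.sum()}, not 1")
    weight = response.activation_weight(condition)

    rng = np.random.default_rng(seed)
    labels = rng.choice(len(populations), size=n_events, p=fractions)
    log_int = np.empty((n_events, len(MARKERS)), dtype=float)
    for i, pop in enumerate(populations):
        idx = np.flatnonzero(labels == i)
        if idx.size == 0:
            continue
        locs = np.array([pop.channels[m][0] for m in MARKERS])
        scales = np.array([pop.channels[m][1] for m in MARKERS])
        if pop.correlation is not None:
            corr = np.full((len(MARKERS),) * 2, pop.correlation)
            np.fill_diagonal(corr, 1.0)
            cov = corr * np.outer(scales, scales)
            log_int[idx] = rng.multivariate_normal(locs, cov, size=idx.size)
        else:
            log_int[idx] = locs + scales * rng.standard_normal((idx.size, len(MARKERS)))

    pop_names = np.array([p.name for p in populations])
    is_baso = pop_names[labels] == "basophil"
    baso_idx = np.flatnonzero(is_baso)
    cd63_col = MARKERS.index(CD63)
    activated = np.zeros(n_events, dtype=bool)
    if baso_idx.size:
        act = rng.random(baso_idx.size) < weight
        activated[baso_idx[act]] = True
        log_int[baso_idx[act], cd63_col] += response.cd63_shift

    cd32_positive = np.zeros(n_events, dtype=bool)
    if cd32_positive_weight is not None and baso_idx.size:
        model = cd32_model or CD32MixtureModel()
        pos = rng.random(baso_idx.size) < cd32_positive_weight
        cd32_col = MARKERS.index(CD32)
        locs = np.where(pos, model.loc_positive, model.loc_negative)
        log_int[baso_idx, cd32_col] = locs + model.scale * rng.standard_normal(baso_idx.size)
        cd32_positive[baso_idx[pos]] = True

    data = pd.DataFrame(10.0 ** log_int, columns=list(MARKERS))
    truth = pd.DataFrame({
        "population": pop_names[labels],
        "activated": activated,
        "cd32_positive": cd32_positive,
    })
    meta = {"condition": condition.label, "seed": int(seed),
            "planted_activation_weight": float(weight)}
    return EventTable(data=data, metadata=meta, truth=truth)


def sample_basophil_cd63(
    response: ResponseModel,
    condition: StimulationCondition,
    n: int,
    seed: int,
    *,
    loc: float = 1.00,
    scale: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """CD63 values (log10 display scale) for ``n`` already-gated basophils.

    Fast path for metric-level simulations that do not need the full
    whole-blood mixture: draws the two-component basophil CD63 mixture
    directly.  Returns the values and the planted activation labels.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w = response.activation_weight(condition)
    act = rng.random(n) < w
    v = loc + scale * rng.standard_normal(n)
    v[act] += response.cd63_shift
    return v, act


def sample_basophil_cd32(
    positive_weight: float,
    n: int,
    seed: int,
    model: CD32MixtureModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CD32 values (log10 display scale) for ``n`` gated basophils."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= positive_weight <= 1.0:
        raise ValueError("positive_weight must be in [0, 1]")
    model = model or CD32MixtureModel()
    rng = np.random.default_rng(seed)
    pos = rng.random(n) < positive_weight
    locs = np.where(pos, model.loc_positive, model.loc_negative)
    return locs + model.scale * rng.standard_normal(n), pos


# ---------------------------------------------------------------------------
# patient / cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSample:
    """Metadata for one sample: enough to regenerate its events exactly."""

    record: SampleRecord
    response: ResponseModel
    planted_weight: float
    seed: int

    def realize(self, populations: list | None = None,
                n_events: int = 100_000) -> EventTable:
        pops = populations if populations is not None else default_populations()
        table = simulate_events(pops, self.response, self.record.condition,
                                n_events, self.seed)
        table.metadata["patient_id"] = self.record.patient_id
        table.metadata["replicate"] = self.record.replicate
        return table


@dataclass
class SimulatedPatient:
    record: PatientRecord
    samples: list


def simulate_patient(
    status: str,
    non_responder: bool = False,
    response: ResponseModel | None = None,
    seed: int = 0,
    *,
    conditions: list | None = None,
    cohort: str = "child",
    patient_id: str | None = None,
    replicates: int = 1,
) -> SimulatedPatient:
    """Plan one patient's sample panel with planted activation weights.

    Allergic responders respond to the wheat-derived allergens (gluten,
    gliadin, wheat extract) and anti-IgE; tolerant patients show only
    baseline activation on allergens but respond to anti-IgE and fMLP;
    non-responders (IgE pathway silent) respond to fMLP only.  A
    tolerant non-responder is rejected as undefined.
    """
    if status not in ("allergic", "tolerant"):
        raise ValueError(f"unknown status {status!r}")
    if non_responder and status == "tolerant":
        raise ValueError("non_responder is only defined for allergic patients")
    base = response if response is not None else ResponseModel()
    conditions = conditions if conditions is not None else default_condition_panel()
    pid = patient_id or f"{status[:3]}-{seed}"
    rng = np.random.default_rng(seed)

    samples = []
    for rep in range(1, replicates + 1):
        for cond in conditions:
            ige_ok = status == "allergic" and not non_responder
            wheat = cond.kind == "allergen" and cond.allergen in WHEAT_ALLERGENS
            eff = replace(
                base,
                responds_allergen=ige_ok and wheat,
                responds_anti_ige=not non_responder,
                responds_fmlp=True,
            )
            sample_seed = int(rng.integers(0, 2 ** 31))
            rec = SampleRecord(patient_id=pid, condition=cond, replicate=rep)
            samples.append(SimulatedSample(
                record=rec, response=eff,
                planted_weight=eff.activation_weight(cond), seed=sample_seed))
    patient = PatientRecord(patient_id=pid, cohort=cohort, status=status,
                            non_responder=non_responder)
    return SimulatedPatient(record=patient, samples=samples)


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    patients: list
    sige: pd.DataFrame  # wide: patient_id + one column per marker (kU/L)

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for s in p.samples:
                c = s.record.condition
                rows.append({
                    "patient_id": p.record.patient_id,
                    "cohort": p.record.cohort,
                    "status": p.record.status,
                    "condition": c.kind,
                    "allergen": c.allergen or "",
                    "concentration_ug_per_ml": c.concentration if c.concentration is not None else "",
                    "replicate": s.record.replicate,
                    "seed": s.seed,
                    "file": s.record.path or "",
                })
        return pd.DataFrame(rows)


def simulate_cohort(spec: CohortSpec, response: ResponseModel | None = None) -> SimulatedCohort:
    """Plan a full cohort: patients, sample panels, planted sIgE panel.

    Exactly ``spec.non_responder_count`` allergic patients are flagged
    (ground truth retained on the patient records).  Per-patient
    response heterogeneity: ``f_max`` uniform over ``spec.f_max_range``
    and ``ec50`` log-normal around the base model's value.  Event tables
    are generated lazily via :meth:`SimulatedSample.realize` or
    :func:`write_cohort`.
    """
    base = response if response is not None else ResponseModel()
    rng = np.random.default_rng(spec.seed)
    statuses = ["allergic"] * spec.n_allergic + ["tolerant"] * spec.n_tolerant
    nr_idx = set(rng.choice(spec.n_allergic, size=spec.non_responder_count,
                            replace=False).tolist()) if spec.non_responder_count else set()

    patients, sige_rows = [], []
    for i, status in enumerate(statuses):
        pid = f"{spec.cohort[0].upper()}{i + 1:03d}"
        f_max = float(rng.uniform(*spec.f_max_range))
        ec50 = float(10 ** rng.normal(np.log10(base.ec50), spec.ec50_log10_sd))
        pr = replace(base, f_max=f_max, ec50=ec50)
        pseed = int(rng.integers(0, 2 ** 31))
        patient = simulate_patient(status, non_responder=(status == "allergic" and i in nr_idx),
                                   response=pr, seed=pseed, cohort=spec.cohort,
                                   patient_id=pid)
        row = {"patient_id": pid}
        for marker, by_status in spec.sige_params.items():
            loc, scale = by_status[status]
            row[marker] = float(10 ** rng.normal(loc, scale))
        patient.record.sige = {m: v for m, v in row.items() if m != "patient_id"}
        sige_rows.append(row)
        patients.append(patient)
    return SimulatedCohort(spec=spec, patients=patients, sige=pd.DataFrame(sige_rows))


def write_cohort(cohort: SimulatedCohort, outdir, *, populations: list | None = None,
                 n_events: int = 100_000, force: bool = False) -> Path:
    """Materialize a cohort to disk: event CSVs, manifest, truth, provenance.

    Layout: ``events/<patient>_<condition>_r<rep>.csv``, ``manifest.csv``,
    ``sige.csv``, ``ground_truth.csv`` (planted per-sample weights and
    per-patient non-responder flags), ``provenance.json``.
    """
    from .events import write_events_csv  # local import to avoid cycle noise

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    (outdir / "events").mkdir(parents=True, exist_ok=True)

    pops = populations if populations is not None else default_populations()
    truth_rows = []
    for p in cohort.patients:
        for s in p.samples:
            fname = f"events/{s.record.patient_id}_{s.record.condition.label}_r{s.record.replicate}.csv"
            table = s.realize(pops, n_events=n_events)
            write_events_csv(table, outdir / fname)
            table.truth.to_csv(outdir / (fname[:-4] + ".truth.csv"), index=False)
            s.record.path = fname
            truth_rows.append({
                "patient_id": p.record.patient_id,
                "condition": s.record.condition.label,
                "replicate": s.record.replicate,
                "planted_weight": s.planted_weight,
                "non_responder": p.record.non_responder,
                "status": p.record.status,
            })
    cohort.manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort.sige.to_csv(outdir / "sige.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    prov = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in dataclasses.asdict(cohort.spec).items()},
        "n_events_per_sample": n_events,
        "package": "binbat",
    }
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))
    return outdir


# ---------------------------------------------------------------------------
# OFC time series (CD32 kinetics)
# ---------------------------------------------------------------------------

OFC_TIMEPOINTS = ("baseline", "post_first_dose", "post_outcome")


@dataclass
class OfcSeries:
    """Three unstimulated samples around one oral food challenge."""

    status: str  # {allergic_reaction, tolerant_uneventful}
    tables: dict  # timepoint -> EventTable
    planted_fractions: dict  # timepoint -> planted CD32+ fraction


def simulate_ofc_series(
    status: str,
    spec: CD32KineticsSpec | None = None,
    seed: int = 0,
    *,
    populations: list | None = None,
    cd32_model: CD32MixtureModel | None = None,
    n_events: int = 100_000,
) -> OfcSeries:
    """Simulate serial unstimulated samples at baseline, +1.5 h, and post-outcome.

    An allergic-reaction series plants a reduced CD32+ basophil fraction
    at the post-outcome timepoint (baseline x downregulation factor); a
    tolerant uneventful series plants stable fractions (times the drift
    factor, 1 by default).
    """
    if status not in ("allergic_reaction", "tolerant_uneventful"):
        raise ValueError(f"unknown OFC series status {status!r}")
    spec = spec or CD32KineticsSpec()
    pops = populations if populations is not None else default_populations()
    rng = np.random.default_rng(seed)
    base = spec.baseline_fraction
    if status == "allergic_reaction":
        post = base * spec.downregulation_factor
    else:
        post = base * spec.tolerant_drift_factor
    planted = {}
    for tp, center in zip(OFC_TIMEPOINTS, (base, base, post)):
        w = center + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        planted[tp] = float(np.clip(w, 0.0, 1.0))

    neg = StimulationCondition("negative_control")
    resp = ResponseModel()
    tables = {}
    for tp in OFC_TIMEPOINTS:
        sub_seed = int(rng.integers(0, 2 ** 31))
        t = simulate_events(pops, resp, neg, n_events, sub_seed,
                            cd32_model=cd32_model,
                            cd32_positive_weight=planted[tp])
        t.metadata["timepoint"] = tp
        tables[tp] = t
    return OfcSeries(status=status, tables=tables, planted_fractions=planted)
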