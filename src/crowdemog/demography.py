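"""Parameterised demographic histories for the European crow complex.

The two competing four-population isolation-with-migration scenarios are

* **genome-wide swamping (GWS)** -- population tree ``((SPA,EURw),(EURns,IRQ))``:
  Western European carrion crows (EURw) split from the Iberian refugium (SPA)
  and were subsequently homogenised by massive gene flow from hooded crows
  (EURns) after secondary contact;
* **locus-specific introgression (LSI)** -- population tree
  ``((IRQ,(EURw,EURns)),SPA)``: EURw shares its most recent common ancestor
  with hooded crows, and only the plumage locus introgressed from Iberia
  across the Pyrenees.

Times are stored in years before present and converted to continuous
(non-integer) generations only at simulation time.  Migration rates are
forward-time donor-to-recipient fractions per generation; the coalescent
engine converts them to backward lineage-movement rates by swapping indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

from .errors import ConfigurationError, ValidationError

__all__ = [
    "GlobalConfig",
    "Population",
    "SplitEvent",
    "MigrationEpoch",
    "DemographicModel",
    "build_gws_model",
    "build_lsi_model",
    "years_to_generations",
    "validate_model",
    "load_model",
    "load_preset",
    "DEFAULT_NE",
    "GWS_FASTSIMCOAL",
    "GWS_JAATHA",
]

#: Default diploid effective sizes used for synthetic work when a parameter
#: set does not supply them.  These are package defaults for simulation
#: experiments, not empirical estimates.
DEFAULT_NE = {
    "SPA": 5e4,
    "IRQ": 2e4,
    "EURw": 2e5,
    "EURns": 4e5,
    "ANC": 1e5,
}

#: Default diploid sample counts of the joint-SFS panel
#: (15 diploids per population, 5 for IRQ).
DEFAULT_SAMPLES = {"SPA": 15, "EURw": 15, "EURns": 15, "IRQ": 5}


@dataclass
class GlobalConfig:
    """Global constants: per-site per-generation mutation probability and
    generation time in years."""

    mutation_rate: float = 3.18e-9
    generation_time: float = 5.79
    rng_seed: Optional[int] = None

    def violations(self):
        out = []
        if not self.mutation_rate > 0:
            out.append("config.mutation_rate: must be > 0")
        if not self.generation_time > 0:
            out.append("config.generation_time: must be > 0")
        return out


@dataclass
class Population:
    """A (possibly growing) population.

    ``growth_rate`` (GR) is the per-generation exponential growth rate acting
    forward in time from ``growth_start_time`` (TEGR, years before present)
    until the present.  Backward in time the size at ``t`` years is
    ``ne_present * exp(-GR * t/g)`` for ``t < growth_start_time`` and constant
    earlier.  ``growth_rate = 0`` means constant size.
    """

    name: str
    ne_present: float
    n_diploid_samples: int = 0
    growth_rate: float = 0.0
    growth_start_time: float = 0.0

    def violations(self):
        out = []
        if not self.ne_present > 0:
            out.append(f"population {self.name}.ne_present: must be > 0")
        if self.n_diploid_samples < 0:
            out.append(f"population {self.name}.n_diploid_samples: must be >= 0")
        if self.growth_start_time < 0:
            out.append(f"population {self.name}.growth_start_time: must be >= 0")
        if self.growth_rate < 0:
            out.append(f"population {self.name}.growth_rate: must be >= 0")
        return out


@dataclass
class SplitEvent:
    """Backward in time, all lineages of ``derived_pop`` join
    ``ancestral_pop`` at ``time`` years before present.

    ``ancestral_ne`` optionally sets the diploid size of the receiving
    lineage from ``time`` backwards, giving each internal branch of the
    population tree its own free size parameter.
    """

    time: float
    derived_pop: str
    ancestral_pop: str
    ancestral_ne: Optional[float] = None


@dataclass
class MigrationEpoch:
    """Migration active on the backward time axis in ``[start_time, end_time)``.

    ``rates`` maps ``(donor, recipient)`` labels -- FORWARD-time direction --
    to per-generation migration fractions.  ``start_time = 0`` is the present.
    """

    start_time: float
    end_time: float
    rates: dict = field(default_factory=dict)

    def normalised_rates(self):
        """Return rates with tuple keys regardless of JSON provenance."""
        out = {}
        for k, v in self.rates.items():
            if isinstance(k, str):
                donor, recipient = k.split("->")
                out[(donor, recipient)] = float(v)
            else:
                out[tuple(k)] = float(v)
        return out


@dataclass
class DemographicModel:
    """A rooted population tree with per-branch sizes, growth, and epochs of
    migration, plus global constants."""

    name: str
    populations: list
    splits: list
    migration_epochs: list
    config: GlobalConfig = field(default_factory=GlobalConfig)

    # -- structure helpers ------------------------------------------------

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def population_names(self):
        return [p.name for p in self.populations]

    def merge_time(self, name: str) -> float:
        """Time at which ``name`` merges into its ancestor (inf for the root)."""
        for s in self.splits:
            if s.derived_pop == name:
                return s.time
        return float("inf")

    def ancestor_path(self, name: str):
        """Sequence of (time, carrier-population) pairs from a leaf to the
        root, following successive merges.  Used for topology comparison."""
        path = []
        current = name
        seen = {name}
        splits = sorted(self.splits, key=lambda s: s.time)
        while True:
            nxt = [s for s in splits if s.derived_pop == current]
            if not nxt:
                return path
            s = nxt[0]
            if s.ancestral_pop in seen:
                # cycle; validate_model reports it, stop walking
                return path
            path.append((s.time, s.ancestral_pop))
            seen.add(s.ancestral_pop)
            current = s.ancestral_pop

    def sample_config(self):
        return {p.name: p.n_diploid_samples for p in self.populations}

    def validate(self):
        return validate_model(self)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "config": asdict(self.config),
            "populations": [asdict(p) for p in self.populations],
            "splits": [asdict(s) for s in self.splits],
            "migration_epochs": [
                {
                    "start_time": e.start_time,
                    "end_time": e.end_time,
                    "rates": {
                        f"{d_}->{r_}": m for (d_, r_), m in e.normalised_rates().items()
                    },
                }
                for e in self.migration_epochs
            ],
        }
        return d

    def to_json(self, path=None, indent=2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicModel":
        return cls(
            name=d["name"],
            config=GlobalConfig(**d.get("config", {})),
            populations=[Population(**p) for p in d["populations"]],
            splits=[SplitEvent(**s) for s in d["splits"]],
            migration_epochs=[
                MigrationEpoch(
                    start_time=e["start_time"],
                    end_time=e["end_time"],
                    rates=dict(e.get("rates", {})),
                )
                for e in d.get("migration_epochs", [])
            ],
        )

    @classmethod
    def from_json(cls, text_or_path) -> "DemographicModel":
        s = str(text_or_path)
        if s.lstrip().startswith("{"):
            return cls.from_dict(json.loads(s))
        with open(s) as fh:
            return cls.from_dict(json.load(fh))


def years_to_generations(t: float, config: GlobalConfig) -> float:
    """Convert years before present to (continuous) generations."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return t / config.generation_time


def validate_model(model: DemographicModel):
    """Return a list of human-readable invariant violations (empty if valid)."""
    v = []
    v.extend(model.config.violations())
    names = model.population_names
    if len(set(names)) != len(names):
        v.append("populations: duplicate names")
    for p in model.populations:
        v.extend(p.violations())

    # splits define a single rooted tree over the populations
    derived_seen = set()
    for s in model.splits:
        if s.time <= 0:
            v.append(f"split {s.derived_pop}->{s.ancestral_pop}: time must be > 0")
        for label in (s.derived_pop, s.ancestral_pop):
            if label not in names:
                v.append(f"split at {s.time}: unknown population '{label}'")
        if s.derived_pop == s.ancestral_pop:
            v.append(f"split at {s.time}: population merges into itself")
        if s.derived_pop in derived_seen:
            v.append(f"split: population '{s.derived_pop}' merges more than once")
        derived_seen.add(s.derived_pop)
        if s.ancestral_ne is not None and not s.ancestral_ne > 0:
            v.append(
                f"split {s.derived_pop}->{s.ancestral_pop}: ancestral_ne must be > 0"
            )

    roots = [n for n in names if n not in derived_seen]
    if len(model.splits) and len(roots) != 1:
        v.append(f"splits: expected a single root population, found {roots}")

    # ancestral population must itself survive past the split time
    for s in model.splits:
        if s.ancestral_pop in names and s.derived_pop in names:
            if model.merge_time(s.ancestral_pop) <= s.time:
                v.append(
                    f"split {s.derived_pop}->{s.ancestral_pop} at {s.time}: "
                    f"ancestral population merges earlier "
                    f"({model.merge_time(s.ancestral_pop)})"
                )

    # migration epochs: rates in [0,1), populations coexist, no per-pair overlap
    pair_intervals = {}
    for i, e in enumerate(model.migration_epochs):
        label = f"migration epoch {i} [{e.start_time}, {e.end_time})"
        if not e.start_time < e.end_time:
            v.append(f"{label}: start_time must be < end_time")
        for (donor, recipient), m in e.normalised_rates().items():
            if donor not in names or recipient not in names:
                v.append(f"{label}: unknown population in pair {donor}->{recipient}")
                continue
            if not (0 <= m < 1):
                v.append(f"{label}: rate {donor}->{recipient}={m} out of [0,1)")
            alive_until = min(model.merge_time(donor), model.merge_time(recipient))
            if e.end_time > alive_until + 1e-9:
                v.append(
                    f"{label}: {donor}->{recipient} extends beyond coexistence "
                    f"(populations merge at {alive_until})"
                )
            key = tuple(sorted((donor, recipient))) + (donor,)
            pair_intervals.setdefault(key, []).append((e.start_time, e.end_time, i))
    for key, ivals in pair_intervals.items():
        ivals.sort()
        for (s0, e0, i0), (s1, e1, i1) in zip(ivals, ivals[1:]):
            if s1 < e0 - 1e-9:
                v.append(
                    f"migration epochs {i0} and {i1} overlap for pair "
                    f"{key[0]}<->{key[1]}"
                )
    return v


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

_TIME_KEYS = ("t_anc", "t_eurns", "t_eurw", "t_contact")
_MIG_KEYS = (
    "m_spa_eurw",
    "m_eurw_spa",
    "m_irq_eurns",
    "m_eurns_irq",
    "m_eurns_eurw",
    "m_eurw_eurns",
)


def _require(params, keys):
    missing = [k for k in keys if k not in params]
    if missing:
        raise ConfigurationError(
            "missing parameter(s): " + ", ".join(sorted(missing))
        )


def _panel(params):
    """Leaf populations with sizes, samples and growth shared by both models."""
    ne = {k: params.get(f"ne_{k.lower()}", DEFAULT_NE[k]) for k in DEFAULT_SAMPLES}
    n = {k: params.get(f"n_{k.lower()}", DEFAULT_SAMPLES[k]) for k in DEFAULT_SAMPLES}
    growth = {
        "EURw": (params.get("gr_eurw", 0.0), params.get("tegr_eurw", 0.0)),
        "EURns": (params.get("gr_eurns", 0.0), params.get("tegr_eurns", 0.0)),
    }
    pops = []
    for name in ("SPA", "EURw", "EURns", "IRQ"):
        gr, tegr = growth.get(name, (0.0, 0.0))
        pops.append(
            Population(
                name=name,
                ne_present=float(ne[name]),
                n_diploid_samples=int(n[name]),
                growth_rate=float(gr),
                growth_start_time=float(tegr),
            )
        )
    return pops


def _config(params):
    return GlobalConfig(
        mutation_rate=params.get("mutation_rate", 3.18e-9),
        generation_time=params.get("generation_time", 5.79),
        rng_seed=params.get("rng_seed"),
    )


def _finish(model):
    violations = validate_model(model)
    if violations:
        raise ValidationError(violations)
    return model


def build_gws_model(params: dict) -> DemographicModel:
    """Genome-wide swamping scenario, topology ``((SPA,EURw),(EURns,IRQ))``.

    Backward in time: EURw merges into the SPA lineage at ``t_eurw``, EURns
    into the IRQ lineage at ``t_eurns``, and the two refugial lineages merge
    at ``t_anc``.  Migration: SPA<->EURw since the EURw split, IRQ<->EURns
    since the EURns split, and EURw<->EURns since the secondary-contact time
    ``t_contact``.

    With ``clamp_epochs=True`` in ``params`` the secondary-contact epoch is
    truncated to the coexistence window of its populations (migration cannot
    outlast a population); otherwise a contact time older than the EURw
    split raises a validation error.  Optimisers explore parameter boxes
    whose corners are infeasible, hence the clamped variant.
    """
    _require(params, _TIME_KEYS + _MIG_KEYS)
    clamp = bool(params.get("clamp_epochs", False))
    t_contact = params["t_contact"]
    if clamp:
        t_contact = min(t_contact, params["t_eurw"], params["t_eurns"])
    anc_low = params.get("ne_anc_low", DEFAULT_NE["ANC"])
    anc_mid = params.get("ne_anc_mid", DEFAULT_NE["ANC"])
    anc_root = params.get("ne_anc_root", DEFAULT_NE["ANC"])
    model = DemographicModel(
        name="gws",
        populations=_panel(params),
        splits=[
            SplitEvent(params["t_eurw"], "EURw", "SPA", ancestral_ne=anc_low),
            SplitEvent(params["t_eurns"], "EURns", "IRQ", ancestral_ne=anc_mid),
            SplitEvent(params["t_anc"], "IRQ", "SPA", ancestral_ne=anc_root),
        ],
        migration_epochs=[
            MigrationEpoch(
                0.0,
                params["t_eurw"],
                {
                    ("SPA", "EURw"): params["m_spa_eurw"],
                    ("EURw", "SPA"): params["m_eurw_spa"],
                },
            ),
            MigrationEpoch(
                0.0,
                params["t_eurns"],
                {
                    ("IRQ", "EURns"): params["m_irq_eurns"],
                    ("EURns", "IRQ"): params["m_eurns_irq"],
                },
            ),
            MigrationEpoch(
                0.0,
                t_contact,
                {
                    ("EURns", "EURw"): params["m_eurns_eurw"],
                    ("EURw", "EURns"): params["m_eurw_eurns"],
                },
            ),
        ],
        config=_config(params),
    )
    return _finish(model)


def build_lsi_model(params: dict) -> DemographicModel:
    """Locus-specific introgression scenario, topology ``((IRQ,(EURw,EURns)),SPA)``.

    The same canonical parameter names are used as for the GWS builder so the
    two models can be fitted with identical free-parameter sets; their
    meaning follows the split depth: ``t_eurw`` is the shallow EURw--EURns
    split, ``t_eurns`` the IRQ--(EURw,EURns) split, ``t_anc`` the root split
    from SPA, and ``t_contact`` the onset of the Pyrenean SPA<->EURw
    exchange.  ``clamp_epochs`` behaves as in :func:`build_gws_model`.
    """
    _require(params, _TIME_KEYS + _MIG_KEYS)
    clamp = bool(params.get("clamp_epochs", False))
    t_contact = params["t_contact"]
    if clamp:
        t_contact = min(t_contact, params["t_eurw"], params["t_anc"])
    anc_low = params.get("ne_anc_low", DEFAULT_NE["ANC"])
    anc_mid = params.get("ne_anc_mid", DEFAULT_NE["ANC"])
    anc_root = params.get("ne_anc_root", DEFAULT_NE["ANC"])
    model = DemographicModel(
        name="lsi",
        populations=_panel(params),
        splits=[
            SplitEvent(params["t_eurw"], "EURw", "EURns", ancestral_ne=anc_low),
            SplitEvent(params["t_eurns"], "IRQ", "EURns", ancestral_ne=anc_mid),
            SplitEvent(params["t_anc"], "EURns", "SPA", ancestral_ne=anc_root),
        ],
        migration_epochs=[
            MigrationEpoch(
                0.0,
                t_contact,
                {
                    ("SPA", "EURw"): params["m_spa_eurw"],
                    ("EURw", "SPA"): params["m_eurw_spa"],
                },
            ),
            MigrationEpoch(
                0.0,
                params["t_eurns"],
                {
                    ("IRQ", "EURns"): params["m_irq_eurns"],
                    ("EURns", "IRQ"): params["m_eurns_irq"],
                },
            ),
            MigrationEpoch(
                0.0,
                params["t_eurw"],
                {
                    ("EURns", "EURw"): params["m_eurns_eurw"],
                    ("EURw", "EURns"): params["m_eurw_eurns"],
                },
            ),
        ],
        config=_config(params),
    )
    return _finish(model)


#: Point estimates of the genome-wide swamping model (SFS-simulation fit),
#: times in years, migration per generation.  Effective sizes are the
#: package's synthetic-work defaults.
GWS_FASTSIMCOAL = {
    "t_anc": 504_000.0,
    "t_eurns": 131_000.0,
    "t_eurw": 34_500.0,
    "t_contact": 20_000.0,
    "m_spa_eurw": 3.16e-4,
    "m_eurw_spa": 1.69e-4,
    "m_irq_eurns": 5.68e-6,
    "m_eurns_irq": 4.52e-5,
    "m_eurns_eurw": 6.94e-4,
    "m_eurw_eurns": 1.29e-4,
    "gr_eurw": 2.35e-4,
    "tegr_eurw": 3_100.0,
    "gr_eurns": 2.54e-4,
    "tegr_eurns": 34_500.0,
}

#: Point estimates from the 14-bin composite-likelihood fit (Jaatha-style).
GWS_JAATHA = {
    "t_anc": 428_000.0,
    "t_eurns": 107_000.0,
    "t_eurw": 31_200.0,
    "t_contact": 30_600.0,
    "m_spa_eurw": 9.70e-5,
    "m_eurw_spa": 9.52e-5,
    "m_irq_eurns": 8.82e-6,
    "m_eurns_irq": 4.41e-5,
    "m_eurns_eurw": 2.42e-4,
    "m_eurw_eurns": 9.32e-5,
    "gr_eurw": 3.74e-5,
    "tegr_eurw": 28_000.0,
    "gr_eurns": 8.74e-5,
    "tegr_eurns": 17_800.0,
}


def load_model(path) -> DemographicModel:
    """Load a model config JSON from disk."""
    return DemographicModel.from_json(path)


def load_preset(name: str) -> DemographicModel:
    """Load one of the shipped preset models.

    Available presets: ``gws_fastsimcoal``, ``gws_jaatha``,
    ``lsi_fastsimcoal``, ``lsi_jaatha``.
    """
    from importlib import resources

    ref = resources.files("crowdemog") / "presets" / f"{name}.json"
    return DemographicModel.from_json(ref.read_text())
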