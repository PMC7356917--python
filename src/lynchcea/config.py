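"""Run configuration: YAML schema, validation, logging and report tables.

A run configuration collects every model input — diagnostic unit costs,
Markov parameter tables, cascade-testing parameters, scenario toggles, PSA
settings and calibration targets — in one structured-text (YAML) document.
Unknown keys are rejected so that typos fail loudly before any computation.
Provenance is split between values printed in the source cost tables
("printed") and documented placeholders ("placeholder"); see
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .cascade import CascadeParams
from .cea import Classification, FrontierResult, PSAConfig, StrategyOutcome
from .diagnostics import CounsellingVariant, ScenarioOptions, Strategy, UnitCosts
from .errors import ConfigError
from .markov import MarkovParams
from .population import CalibrationTargets, Genotype, PETALS_TARGETS

logger = logging.getLogger("lynchcea")

STRATEGY_LABELS = {
    Strategy.S0_NO_TESTING: "Strategy 0: No testing",
    Strategy.S1_MSI: "Strategy 1: MSI",
    Strategy.S2_MSI_METH: "Strategy 2: MSI and MLH1 methylation",
    Strategy.S3_MANCHESTER: "Strategy 3: IHC and MLH1 methylation",
    Strategy.S4_DIRECT_NGS: "Strategy 4: Direct NGS",
}


@dataclass(frozen=True)
class RunConfig:
    unit_costs: UnitCosts = field(default_factory=UnitCosts)
    markov: MarkovParams = field(default_factory=MarkovParams)
    cascade: CascadeParams = field(default_factory=CascadeParams)
    scenario: ScenarioOptions = field(default_factory=ScenarioOptions)
    psa: PSAConfig = field(default_factory=PSAConfig)
    targets: CalibrationTargets = PETALS_TARGETS
    seed: int = 0
    output_dir: str = "outputs"


def default_config() -> RunConfig:
    return RunConfig()


# ---------------------------------------------------------------------------
# dict <-> dataclass with unknown-key rejection
# ---------------------------------------------------------------------------


def _build(cls, data: dict, section: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}': {exc}") from exc


def _targets_from_dict(data: dict) -> CalibrationTargets:
    data = dict(data)
    if "genotype_split" in data:
        data["genotype_split"] = {
            Genotype(k): int(v) for k, v in data["genotype_split"].items()
        }
    t = _build(CalibrationTargets, data, "targets")
    t.validate()
    return t


def _scenario_from_dict(data: dict) -> ScenarioOptions:
    data = dict(data)
    if "counselling_cost_variant" in data:
        data["counselling_cost_variant"] = CounsellingVariant(
            data["counselling_cost_variant"]
        )
    return _build(ScenarioOptions, data, "scenario")


def _markov_from_dict(data: dict) -> MarkovParams:
    data = dict(data)
    for key in ("stage_dist_surv", "stage_dist_nosurv", "stage_mortality"):
        if key in data:
            data[key] = tuple(float(x) for x in data[key])
    if "incidence" in data:
        data["incidence"] = {
            str(g): [(int(lo), float(r)) for lo, r in bands]
            for g, bands in data["incidence"].items()
        }
    if "crc_cost" in data:
        data["crc_cost"] = {
            int(lo): [float(c) for c in row] for lo, row in data["crc_cost"].items()
        }
    return _build(MarkovParams, data, "markov")


def _cascade_from_dict(data: dict) -> CascadeParams:
    data = dict(data)
    for key in ("quintile_ages", "sexes"):
        if key in data:
            data[key] = tuple(data[key])
    return _build(CascadeParams, data, "cascade")


_SECTIONS = {
    "unit_costs": lambda d: _build(UnitCosts, d, "unit_costs"),
    "markov": _markov_from_dict,
    "cascade": _cascade_from_dict,
    "scenario": _scenario_from_dict,
    "psa": lambda d: _build(PSAConfig, d, "psa"),
    "targets": _targets_from_dict,
}


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    known = set(_SECTIONS) | {"seed", "output_dir"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, builder in _SECTIONS.items():
        if name in data:
            kwargs[name] = builder(data[name])
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {plain(k): plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(x) for x in obj]
        if hasattr(obj, "value"):  # Enum
            return obj.value
        return obj

    return {
        "unit_costs": plain(cfg.unit_costs),
        "markov": plain(cfg.markov),
        "cascade": plain(cfg.cascade),
        "scenario": plain(cfg.scenario),
        "psa": plain(cfg.psa),
        "targets": plain(cfg.targets),
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
    }


def load_config(path) -> RunConfig:
    """Read and fully validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = config_from_dict(data if data is not None else {})
    logger.info("loaded config %s (sha256 %s)", path, config_hash(cfg)[:12])
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def setup_logging(logfile: Optional[str] = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _format_block(outcomes, result: FrontierResult, effect_label: str) -> list[str]:
    lines = []
    for o in sorted(outcomes, key=lambda o: (o.effect, o.cost)):
        cls = result.classification[o.strategy]
        if cls is Classification.ON_FRONTIER:
            icer = result.icers.get(o.strategy)
            icer_txt = "—" if icer is None else f"{round_half_away(icer):,}"
        elif cls is Classification.DOMINATED:
            icer_txt = "Dominated"
        else:
            icer_txt = "Extendedly dominated"
        label = STRATEGY_LABELS[o.strategy]
        eff = f"{o.effect:g}" if float(o.effect).is_integer() else f"{o.effect:.3f}"
        lines.append(f"{label:<40} {o.cost:>12,.0f} {eff:>10} {icer_txt:>22}")
    return lines


def render_table3(
    short_term: Optional[tuple] = None,
    lifetime: Optional[tuple] = None,
) -> str:
    """Publication-style deterministic base-case results table.

    Each argument is ``(outcomes, frontier_result)``.  Strategies are listed
    in ascending order of effectiveness; ICERs are rounded to the pound and
    computed versus the next most effective strategy on the frontier.
    """
    from .cea import frontier as _frontier

    if short_term is None and lifetime is None:
        raise ConfigError("nothing to render")
    out = ["Deterministic base case cost-effectiveness analysis", ""]
    if short_term is not None:
        outcomes, result = short_term
        out.append(
            f"{'Short-term':<40} {'Cost (£)':>12} {'Cases':>10} {'ICER (£/case)':>22}"
        )
        out.extend(_format_block(outcomes, result, "cases"))
        out.append("")
    if lifetime is not None:
        outcomes, result = lifetime
        out.append(
            f"{'Lifetime':<40} {'Cost (£)':>12} {'QALYs':>10} {'ICER (£/QALY)':>22}"
        )
        out.extend(_format_block(outcomes, result, "qalys"))
        out.append("")
    return "\n".join(out)
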