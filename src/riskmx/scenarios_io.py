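"""Scenario/geometry configuration I/O and synthetic-input generators.

Configuration lives in a single YAML mapping with a versioned ``schema``
key.  Unknown keys are errors, not warnings: these files encode clinical
inputs and silent typos (``wieghts:``) must not pass.  All percentages are
numbers in percent units (6.5 means 6.5 %), never fractions.

Two bundled configs transcribe the published worked examples:

* ``calcium_preeclampsia`` — preeclampsia incidence without (6.5 %) and
  with (4.8 %) universal calcium supplementation, with the maternal
  impact rows from the national birth registry estimates.
* ``sga_thresholds`` — small-for-gestational-age screening at the 10th
  (10 % prevalence) vs the 5th (5 %) growth centile, with neonatal
  outcome rows.

Random generators (Dirichlet scenario rows, discretised-normal Likert
tables) support property testing; both are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .matrix_core import (
    DEFAULT_GEOMETRY,
    ImpactLevel,
    MatrixGeometry,
    ProbabilityBand,
    RiskCategory,
    RiskMatrixError,
)
from .population_risk import DEFAULT_ROW_SUM_TOLERANCE, Scenario, validate_distribution

SCHEMA_VERSION = 1


class ConfigError(RiskMatrixError):
    """Raised on unparseable, unversioned or invalid configuration."""


@dataclass(frozen=True)
class Pairing:
    """A named baseline/intervention pair with its invasiveness class."""

    name: str
    baseline: str
    intervention: str
    invasiveness: str


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated configuration: geometry, scenarios, optional pairings."""

    geometry: MatrixGeometry
    scenarios: tuple[Scenario, ...]
    pairings: tuple[Pairing, ...] = ()
    tolerance: float = DEFAULT_ROW_SUM_TOLERANCE
    source: str = "<memory>"

    def scenario(self, name: str) -> Scenario:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise ConfigError(
            f"unknown scenario {name!r}; have {[s.name for s in self.scenarios]}"
        )


_TOP_KEYS = {"schema", "tolerance", "geometry", "scenarios", "pairings"}
_GEOM_KEYS = {"bands", "impact_labels", "categories"}
_SCEN_KEYS = {"event_probability", "weights"}
_PAIR_KEYS = {"baseline", "intervention", "invasiveness"}


def _reject_unknown(mapping: Mapping, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {where}")


def _build_geometry(raw: Mapping | None) -> MatrixGeometry:
    if raw is None:
        return DEFAULT_GEOMETRY
    _reject_unknown(raw, _GEOM_KEYS, "geometry")
    bands = DEFAULT_GEOMETRY.bands
    if "bands" in raw:
        bands = tuple(
            ProbabilityBand(int(b["index"]), str(b["label"]),
                            float(b["lower_pct"]), float(b["upper_pct"]))
            for b in raw["bands"]
        )
    levels = DEFAULT_GEOMETRY.impact_levels
    if "impact_labels" in raw:
        labels = list(raw["impact_labels"])
        if len(labels) != 5:
            raise ConfigError(f"impact_labels needs 5 entries, got {len(labels)}")
        levels = tuple(ImpactLevel(i + 1, str(lbl)) for i, lbl in enumerate(labels))
    cats = DEFAULT_GEOMETRY.categories
    if "categories" in raw:
        cats = tuple(
            RiskCategory(str(c["name"]), str(c["color_label"]),
                         int(c["score_min"]), int(c["score_max"]), int(c["rank"]))
            for c in raw["categories"]
        )
    return MatrixGeometry(bands=bands, impact_levels=levels, categories=cats)


def parse_config(raw: Mapping, source: str = "<memory>") -> ScenarioConfig:
    """Validate a parsed YAML mapping into a :class:`ScenarioConfig`."""
    if not isinstance(raw, Mapping) or not raw:
        raise ConfigError(f"{source}: config must be a non-empty mapping")
    _reject_unknown(raw, _TOP_KEYS, source)
    if raw.get("schema") != SCHEMA_VERSION:
        raise ConfigError(
            f"{source}: missing or unsupported schema version "
            f"(expected schema: {SCHEMA_VERSION}, got {raw.get('schema')!r})"
        )
    tolerance = float(raw.get("tolerance", DEFAULT_ROW_SUM_TOLERANCE))
    geometry = _build_geometry(raw.get("geometry"))
    scen_raw = raw.get("scenarios")
    if not scen_raw:
        raise ConfigError(f"{source}: config defines no scenarios")
    scenarios = []
    for name, body in scen_raw.items():
        _reject_unknown(body, _SCEN_KEYS, f"scenario {name!r}")
        try:
            scenarios.append(
                Scenario.from_weights(
                    name=str(name),
                    event_probability=float(body["event_probability"]),
                    raw_weights=[float(w) for w in body["weights"]],
                    tolerance=tolerance,
                    geometry=geometry,
                )
            )
        except KeyError as exc:
            raise ConfigError(f"{source}: scenario {name!r} missing key {exc}") from exc
        except RiskMatrixError as exc:
            raise ConfigError(f"{source}: scenario {name!r}: {exc}") from exc
    names = {s.name for s in scenarios}
    pairings = []
    for pname, body in (raw.get("pairings") or {}).items():
        _reject_unknown(body, _PAIR_KEYS, f"pairing {pname!r}")
        for role in ("baseline", "intervention"):
            if body[role] not in names:
                raise ConfigError(
                    f"{source}: pairing {pname!r} references unknown scenario "
                    f"{body[role]!r}"
                )
        pairings.append(
            Pairing(str(pname), str(body["baseline"]), str(body["intervention"]),
                    str(body["invasiveness"]))
        )
    return ScenarioConfig(
        geometry=geometry,
        scenarios=tuple(scenarios),
        pairings=tuple(pairings),
        tolerance=tolerance,
        source=source,
    )


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario config file (YAML)."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if raw is None:
        raise ConfigError(f"{path}: file is empty")
    return parse_config(raw, source=str(path))


def write_config(config: ScenarioConfig, path) -> None:
    """Serialise a config back to YAML; round-trips through load_config."""
    doc = {
        "schema": SCHEMA_VERSION,
        "tolerance": config.tolerance,
        "geometry": {
            "bands": [
                {"index": b.index, "label": b.label,
                 "lower_pct": b.lower_pct, "upper_pct": b.upper_pct}
                for b in config.geometry.bands
            ],
            "impact_labels": [l.role_label for l in config.geometry.impact_levels],
            "categories": [
                {"name": c.name, "color_label": c.color_label,
                 "score_min": c.score_min, "score_max": c.score_max, "rank": c.rank}
                for c in config.geometry.categories
            ],
        },
        "scenarios": {
            s.name: {
                "event_probability": s.event_probability,
                "weights": list(s.distribution.raw_weights),
            }
            for s in config.scenarios
        },
        "pairings": {
            p.name: {"baseline": p.baseline, "intervention": p.intervention,
                     "invasiveness": p.invasiveness}
            for p in config.pairings
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def bundled_config_path(name: str) -> Path:
    """Path of a bundled config (``calcium_preeclampsia`` or ``sga_thresholds``)."""
    ref = resources.files("riskmx.data") / f"{name}.yaml"
    if not ref.is_file():
        raise ConfigError(f"no bundled config named {name!r}")
    return Path(str(ref))


def load_bundled_config(name: str) -> ScenarioConfig:
    """Load one of the bundled worked-example configs."""
    return load_config(bundled_config_path(name))


def fixture_scenarios() -> list[Scenario]:
    """The four published worked-example scenarios.

    calcium-absent (6.5 %; 28/53/15/4.3/0.1), calcium-present (4.8 %;
    28/54/15/3.4/0.02), sga-p10 (10 %; 23/63/13/0.3/0.6) and sga-p5
    (5 %; 16/50/30/1.4/2.6), weights at full printed precision.
    """
    out: list[Scenario] = []
    for cfg_name in ("calcium_preeclampsia", "sga_thresholds"):
        out.extend(load_bundled_config(cfg_name).scenarios)
    return out


def random_scenario(
    seed: int,
    band: int | None = None,
    concentration: float = 1.0,
    geometry: MatrixGeometry = DEFAULT_GEOMETRY,
) -> Scenario:
    """Deterministic random scenario for property testing.

    Weights are a symmetric Dirichlet(``concentration``) draw scaled to
    100 %; the event probability is uniform within the chosen (or
    uniformly random) band's interval.
    """
    if concentration <= 0:
        raise RiskMatrixError(f"Dirichlet concentration must be > 0, got {concentration}")
    rng = np.random.default_rng(seed)
    band_idx = int(band) if band is not None else int(rng.integers(1, 6))
    if not 1 <= band_idx <= 5:
        raise RiskMatrixError(f"band index must be 1-5, got {band_idx}")
    b = geometry.bands[band_idx - 1]
    # strictly inside the interval, away from boundary conventions
    lo, hi = b.lower_pct, b.upper_pct
    p = float(lo + (hi - lo) * rng.uniform(0.05, 0.95))
    weights = rng.dirichlet(np.full(5, concentration)) * 100.0
    return Scenario.from_weights(
        name=f"random-{seed}", event_probability=p, raw_weights=weights,
        geometry=geometry,
    )


def random_survey(
    seed: int,
    effect_profile: Sequence[tuple[float, float]],
    n_respondents: int = 200,
) -> pd.DataFrame:
    """Synthetic long-format Likert survey table.

    One statement per ``(true mean, true sd)`` entry; responses are
    normal draws rounded to the nearest integer and clipped to 1-10.
    Emulates independent raters with a shared latent opinion; it does not
    model rater correlation or ordinal response styles.
    """
    if n_respondents < 2:
        raise RiskMatrixError(f"need >= 2 respondents, got {n_respondents}")
    if not effect_profile:
        raise RiskMatrixError("effect_profile must name at least one statement")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (mu, sd) in enumerate(effect_profile, start=1):
        if sd < 0:
            raise RiskMatrixError(f"true SD must be non-negative, got {sd}")
        draws = np.clip(np.rint(rng.normal(mu, sd, size=n_respondents)), 1, 10)
        rows.extend(
            {"statement_id": f"S{i}", "respondent_id": f"R{j + 1}",
             "score": int(v)}
            for j, v in enumerate(draws)
        )
    return pd.DataFrame(rows, columns=["statement_id", "respondent_id", "score"])
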