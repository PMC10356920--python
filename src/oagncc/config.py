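"""Loading of the study's code-set configuration.

The default configuration (shipped as ``codesets.yaml``) carries the
dyslipidemia entry code, the composite outcome's three channels, the six
statin substance codes, and the fourteen baseline covariates in their fixed
reporting order.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

from .claims import CodeSet, CodeSystem, ConfigError, StatinCatalog

#: fixed order of the fourteen adjustment covariates
COVARIATE_ORDER = (
    "diabetes_mellitus",
    "hypertension",
    "hypotension",
    "hyperuricemia_gout",
    "arrhythmia_heart_failure",
    "ischemic_heart_disease",
    "cerebrovascular_disease",
    "transient_ischemic_attack",
    "migraine",
    "obstructive_sleep_apnea",
    "myopia",
    "infectious_inflammatory",
    "beta_blocker",
    "steroid",
)


@dataclass(frozen=True)
class CovariateDef:
    name: str
    kind: str  # "diagnosis" | "diagnosis_composite" | "medication"
    code_sets: tuple[CodeSet, ...]  # composites carry one set per sub-group


@dataclass(frozen=True)
class CodeConfig:
    dyslipidemia: CodeSet
    outcome_diagnosis: CodeSet
    outcome_drug: CodeSet
    outcome_surgery: CodeSet
    statins: StatinCatalog
    covariates: tuple[CovariateDef, ...]

    def covariate(self, name: str) -> CovariateDef:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)


def _code_set(name: str, node: dict) -> CodeSet:
    try:
        system = CodeSystem(node["system"])
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"code set {name!r}: bad or missing system") from exc
    return CodeSet(name, system, tuple(str(c) for c in node["codes"]))


def load_code_config(path: str | Path | None = None) -> CodeConfig:
    """Load a code configuration; defaults to the packaged ``codesets.yaml``."""
    if path is None:
        text = (
            importlib.resources.files("oagncc").joinpath("codesets.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    covariates: list[CovariateDef] = []
    for node in raw["covariates"]:
        name = node["name"]
        kind = node["kind"]
        system = CodeSystem(node["system"])
        if kind == "diagnosis_composite":
            sets = tuple(
                CodeSet(f"{name}:{gname}", system, tuple(str(c) for c in codes))
                for gname, codes in node["groups"].items()
            )
        elif kind in ("diagnosis", "medication"):
            sets = (CodeSet(name, system, tuple(str(c) for c in node["codes"])),)
        else:
            raise ConfigError(f"covariate {name!r}: unknown kind {kind!r}")
        covariates.append(CovariateDef(name, kind, sets))

    names = tuple(c.name for c in covariates)
    if names != COVARIATE_ORDER:
        raise ConfigError(
            f"covariates must appear in the fixed order {COVARIATE_ORDER}, got {names}"
        )

    return CodeConfig(
        dyslipidemia=_code_set("dyslipidemia", raw["dyslipidemia"]),
        outcome_diagnosis=_code_set("outcome_diagnosis", raw["outcome"]["diagnosis"]),
        outcome_drug=_code_set("outcome_drug", raw["outcome"]["drug"]),
        outcome_surgery=_code_set("outcome_surgery", raw["outcome"]["surgery"]),
        statins=StatinCatalog(dict(raw["statins"])),
        covariates=tuple(covariates),
    )
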