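"""Whole-config validation returning findings instead of raising.

Structural problems (negative prices, wrong types) are rejected at parse
time by the pydantic models. This module checks the semantic ranges and
cross-references that a structurally complete configuration can still
violate, and reports them all at once so a user can fix a config in one
pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .models import FarmConfig

Severity = Literal["error", "warning"]


@dataclass(frozen=True)
class Finding:
    severity: Severity
    path: str  # dotted key path of the offending field
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity.upper()}: {self.path}: {self.message}"


def _rate_in_unit_interval(
    findings: list[Finding], value: float, path: str, *,
    open_top: bool = False,
) -> None:
    top_ok = value < 1.0 if open_top else value <= 1.0
    if not (0.0 <= value and top_ok):
        bound = "[0, 1)" if open_top else "[0, 1]"
        findings.append(
            Finding("error", path, f"rate {value} outside {bound}")
        )


def validate_config(cfg: FarmConfig) -> list[Finding]:
    """Check rate ranges and register cross-references.

    Returns an empty list iff the configuration satisfies every
    invariant. Error findings make the config uncomputable; warnings
    flag values that are legal but suspicious (e.g. an annual capital
    remuneration rate above 100%).
    """
    findings: list[Finding] = []
    herd = cfg.herd

    _rate_in_unit_interval(
        findings, herd.farrowing_rate, "herd.farrowing_rate"
    )
    if herd.farrowing_rate == 0 and herd.sows_in_production > 0:
        findings.append(
            Finding(
                "warning",
                "herd.farrowing_rate",
                "zero farrowing rate: no piglets will be produced",
            )
        )

    seen: set[tuple[str, str]] = set()
    for i, ph in enumerate(herd.phases):
        path = f"herd.phases[{i}]"
        _rate_in_unit_interval(
            findings, ph.mortality, f"{path}.mortality", open_top=True
        )
        if ph.key in seen:
            findings.append(
                Finding(
                    "error",
                    path,
                    f"duplicate (category, phase) pair {ph.key}",
                )
            )
        seen.add(ph.key)

    for i, cull in enumerate(herd.culls):
        _rate_in_unit_interval(
            findings,
            cull.annual_cull_rate,
            f"herd.culls[{i}].annual_cull_rate",
        )

    # Register rows must point at a herd cell so the costing pass can
    # find the consuming population.
    keys = herd.phase_keys()
    for name, lines in (("diets", cfg.diets), ("health", cfg.health)):
        for i, line in enumerate(lines):
            if (line.category, line.phase) not in keys:
                findings.append(
                    Finding(
                        "error",
                        f"{name}[{i}]",
                        "references unknown herd cell "
                        f"({line.category!r}, {line.phase!r})",
                    )
                )

    _rate_in_unit_interval(findings, cfg.utilities.share, "utilities.share")
    for i, fuel in enumerate(cfg.fuels):
        _rate_in_unit_interval(findings, fuel.share, f"fuels[{i}].share")

    for i, asset in enumerate(cfg.assets):
        path = f"assets[{i}]"
        if asset.useful_life_years <= 0:
            findings.append(
                Finding(
                    "error",
                    f"{path}.useful_life_years",
                    "useful life must be positive",
                )
            )
        _rate_in_unit_interval(
            findings, asset.residual_rate, f"{path}.residual_rate",
            open_top=True,
        )

    opp = cfg.opportunity
    if not opp.rates_above_one_ok:
        for field in ("fixed_capital_rate", "working_capital_rate"):
            value = getattr(opp, field)
            if value > 1.0:
                findings.append(
                    Finding(
                        "warning",
                        f"opportunity.{field}",
                        f"annual rate {value} exceeds 100%; set "
                        "rates_above_one_ok if intended",
                    )
                )

    return findings


def errors(findings: list[Finding]) -> list[Finding]:
    return [f for f in findings if f.severity == "error"]
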