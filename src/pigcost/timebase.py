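"""Time-basis and unit constants of the weekly cost ledger.

Every cost in the model is expressed per *weekly batch*: the cohort of
market pigs sold in one week. Inputs are entered on the basis on which a
farm actually records them (per month for salaries, utilities and fuel;
per year for depreciation, taxes and capital remuneration) and converted
to a weekly figure with two fixed divisors:

* ``omega`` — weeks per month. The model uses the printed managerial
  constant 4.345, not a recomputed value, so that monthly-to-weekly
  conversion is exactly ``X / 4.345``.
* ``phi`` — weeks in a 365-day year, i.e. ``365 / 7``. Annual amounts
  convert to weekly as ``X * 7 / 365``.

Market-hog prices in Brazil are commonly quoted per *arroba*, a
livestock weight unit of exactly 18.75 kg.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Weeks per month used for monthly-to-weekly conversion.
WEEKS_PER_MONTH: float = 4.345

#: Weeks in a 365-day year, used for annual-to-weekly conversion.
WEEKS_PER_YEAR: float = 365.0 / 7.0

#: Kilograms per arroba (Brazilian livestock weight unit).
ARROBA_KG: float = 18.75


@dataclass(frozen=True)
class TimeBasis:
    """Bundle of the conversion constants, passed through the engine.

    The defaults are the model's fixed values; they are exposed as a
    dataclass only so that the conversion basis travels explicitly
    through function signatures rather than as hidden globals.
    """

    omega: float = WEEKS_PER_MONTH
    phi: float = WEEKS_PER_YEAR
    arroba_kg: float = ARROBA_KG

    def weekly_from_monthly(self, amount: float) -> float:
        return amount / self.omega

    def weekly_from_annual(self, amount: float) -> float:
        return amount / self.phi


#: Shared default instance.
TIME_BASIS = TimeBasis()
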