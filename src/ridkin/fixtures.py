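"""Reference parameter sets.

No published fit of the two-store whole-body model prints its rate
constants, so the package ships an illustrative set constructed from a
target steady-state geometry.  It is calibrated to the qualitative
behaviour expected for children with relatively high vitamin A intakes:

* plasma specific activity falls steeply for the first days, then bends as
  tracer recycles back from stores;
* plasma and store SA cross over near day 12;
* the fraction of the dose in stores (Fa) is a flat curve near 0.73-0.74;
* dietary input into plasma R(5,4) is exactly 25% of input from stores
  R(5,6), so the equilibrium plasma/store SA ratio is 0.8.

The set is illustrative, not a re-fit of any cohort.
"""

from __future__ import annotations

from .parameters import KineticParameters

__all__ = ["default_parameters", "DEFAULT_MASSES"]

#: Steady-state tracee masses (µmol) the default set was designed around:
#: plasma 1.25, large store 1750, small fast store 3.
DEFAULT_MASSES: dict[str, float] = {"m_5": 1.25, "m_6": 1750.0, "m_7": 3.0}


def default_parameters() -> KineticParameters:
    """Return the package's reference kinetic parameter set.

    Construction: dietary intake 2.27 µmol/d (~650 µg retinol activity
    equivalents), absorption efficiency 0.8, so absorbed dietary inflow
    R(5,4) = 1.816 µmol/d.  Store-to-plasma inflow R(5,6) is set to four
    times R(5,4) (equilibrium SA ratio 0.8).  Irreversible disposal is
    split 66% from store 6 and 34% from plasma via component 8.  The small
    store exchanges 1 µmol/d with plasma and holds 3 µmol, giving the
    fast (~day-scale) mixing phase; the large store holds 1750 µmol,
    placing the plasma/store SA crossover near day 12.
    """
    m_5, m_6, m_7 = DEFAULT_MASSES["m_5"], DEFAULT_MASSES["m_6"], DEFAULT_MASSES["m_7"]
    intake = 2.27  # µmol/d
    absorb = 0.8
    r_5_4 = absorb * intake  # absorbed dietary inflow to plasma, µmol/d
    r_5_6 = 4.0 * r_5_4  # store 6 -> plasma recycling flux
    r_0_6 = 0.66 * r_5_4  # store-side disposal
    r_8_5 = r_5_4 - r_0_6  # plasma-side disposal closes whole-body balance
    r_57 = 1.0  # plasma <-> small store exchange flux
    return KineticParameters(
        absorption_efficiency=absorb,
        delay_time=0.25,
        l_5_4=5.0,
        l_6_5=(r_5_6 + r_0_6) / m_5,
        l_7_5=r_57 / m_5,
        l_8_5=r_8_5 / m_5,
        l_5_6=r_5_6 / m_6,
        l_5_7=r_57 / m_7,
        l_0_6=r_0_6 / m_6,
        dietary_intake=intake,
        dose=1.0,
    )
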