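import numpy as np
import pytest

import hillmix as hm

PAIRS = [
    ("midazolam", "propofol"),
    ("midazolam", "alfentanil"),
    ("propofol", "alfentanil"),
]


@pytest.fixture(scope="session")
def anesthetics():
    return hm.load_anesthetics()


@pytest.fixture(scope="session")
def published_curves(anesthetics):
    """Published pure-compound Hill parameters, in table compound order."""
    return [hm.ANESTHETICS_PURE_HILL[c] for c in anesthetics.compounds]


@pytest.fixture(scope="session")
def fitted_curves(anesthetics):
    """Pure curves refitted from the single-drug rows (e0=0, emax=1 fixed)."""
    out = []
    for name in anesthetics.compounds:
        curve, _ = hm.fit_pure(anesthetics, name, fix_e0=0.0, fix_emax=1.0)
        out.append(curve)
    return out


@pytest.fixture(scope="session")
def binary_fits(anesthetics, fitted_curves):
    """3-interaction-parameter fits for each anesthetic pair."""
    by = {c.name: c for c in fitted_curves}
    fits = {}
    for pair in PAIRS:
        sub = anesthetics.restrict(list(pair))
        mask = hm.ParameterMask.interactions_only(sub.compounds)
        fits[pair] = hm.fit_mixture(
            sub, [by[n] for n in sub.compounds], mask, seed=1
        )
    return fits


@pytest.fixture(scope="session")
def ternary_fit(anesthetics, fitted_curves):
    """11-parameter ternary fit: all pairwise triples + slope and position
    three-way interactions (the three-way max-effect term excluded)."""
    names = anesthetics.compounds
    ids = set()
    for pair in PAIRS:
        lab = "+".join(sorted(pair))
        ids |= {f"demax[{lab}]", f"dslope[{lab}]", f"dm[{lab}]"}
    lab3 = "+".join(sorted(names))
    ids |= {f"dslope[{lab3}]", f"dm[{lab3}]"}
    mask = hm.ParameterMask(names, ids)
    return hm.fit_mixture(anesthetics, fitted_curves, mask, seed=1)


@pytest.fixture(scope="session")
def dose_bounds(anesthetics):
    """Experimental dose range (lowest nonzero, highest) per compound."""
    return {c: anesthetics.dose_range(c) for c in anesthetics.compounds}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
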