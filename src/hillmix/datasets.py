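"""Packaged datasets and a synthetic dose-response generator.

:func:`load_anesthetics` returns the hypnosis study of three intravenous
anesthetics (midazolam, propofol, alfentanil; doses in mg/kg, quantal
effect fractions 0..1): five single-drug series rows per compound (seven
for propofol), three binary fixed-ratio rays and a ternary ray — the
canonical worked example for binary and ternary interaction fitting.

:func:`generate` draws tables from a known ground-truth
:class:`~hillmix.models.MixtureModel` for recovery and calibration
studies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .models import HillCurve, MixtureModel, u_ricc
from .table import DoseResponseTable

__all__ = [
    "load_anesthetics",
    "ANESTHETICS_SHA256",
    "ANESTHETICS_PURE_HILL",
    "SyntheticSpec",
    "generate",
    "factorial_design",
    "ray_design",
    "single_drug_design",
]

# Digest of the packaged file; the fixture-integrity test pins it.
ANESTHETICS_SHA256 = "85ee0ec65634660c5aec1fc8686cae4093fd5e5599ef9ace26be65328130d1dd"

# Published pure-compound Hill parameters for this dataset (median-effect
# dose in mg/kg, slope), with zero baseline and full maximum: the quantal
# endpoint fixes e0 = 0 and emax = 1.
ANESTHETICS_PURE_HILL = {
    "midazolam": HillCurve("midazolam", 0.0, 1.0, 0.144, 4.8),
    "propofol": HillCurve("propofol", 0.0, 1.0, 1.078, 11.1),
    "alfentanil": HillCurve("alfentanil", 0.0, 1.0, 0.093, 5.7),
}


def _fixture_bytes() -> bytes:
    return (resources.files("hillmix") / "data" / "anesthetics.csv").read_bytes()


def anesthetics_digest() -> str:
    return hashlib.sha256(_fixture_bytes()).hexdigest()


def load_anesthetics() -> DoseResponseTable:
    """The packaged anesthetics dose-effect table (doses mg/kg)."""
    with resources.as_file(resources.files("hillmix") / "data" / "anesthetics.csv") as p:
        df = pd.read_csv(p, comment="#")
    return DoseResponseTable.from_dataframe(
        df, ["midazolam", "propofol", "alfentanil"], units="mg/kg"
    )


# ---------------------------------------------------------------------------
# synthetic tables
# ---------------------------------------------------------------------------

def single_drug_design(ec50s, n_doses: int = 6, span: float = 4.0) -> np.ndarray:
    """Per-compound log-spaced dose series around each EC50 (others zero)."""
    ec50s = np.asarray(ec50s, dtype=float)
    n = ec50s.size
    rows = []
    for i, e in enumerate(ec50s):
        for d in np.geomspace(e / span, e * span, n_doses):
            row = np.zeros(n)
            row[i] = d
            rows.append(row)
    return np.array(rows)


def factorial_design(ec50s, n_per_axis: int = 5, span: float = 3.0) -> np.ndarray:
    """Full factorial grid of joint doses, log-spaced around the EC50s."""
    ec50s = np.asarray(ec50s, dtype=float)
    axes = [np.geomspace(e / span, e * span, n_per_axis) for e in ec50s]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=-1)


def ray_design(ec50s, fractions, n_levels: int = 6, span: float = 4.0) -> np.ndarray:
    """Fixed-ratio ray: total EC50-scaled dose varied, split by ``fractions``."""
    ec50s = np.asarray(ec50s, dtype=float)
    f = np.asarray(fractions, dtype=float)
    f = f / f.sum()
    totals = np.geomspace(1.0 / span, span, n_levels)
    return np.array([t * f * ec50s for t in totals])


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic dose-response table.

    ``model`` is the ground truth; ``design`` the dose layout (rows x n);
    Gaussian noise of SD ``noise_sd`` is added to the noiseless surface and
    optionally clipped back into [0, 1].
    """

    model: MixtureModel
    design: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0
    clip: bool = True
    units: str = ""

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.design.ndim != 2 or self.design.shape[1] != self.model.n:
            raise ValueError("design shape does not match model compounds")


def generate(spec: SyntheticSpec) -> DoseResponseTable:
    """Draw a table from the ground-truth surface; reproducible per seed.

    The returned table's ``meta['truth']`` holds the generating model so
    recovery studies can score estimates against it.
    """
    clean = u_ricc(spec.model, spec.design)
    rng = np.random.default_rng(spec.seed)
    eff = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    if spec.clip:
        eff = np.clip(eff, 0.0, 1.0)
    table = DoseResponseTable(spec.model.names, spec.design, eff, spec.units)
    table.meta["truth"] = spec.model
    table.meta["noise_sd"] = spec.noise_sd
    table.meta["seed"] = spec.seed
    return table
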