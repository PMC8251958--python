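"""Synthetic data generators with known ground truth.

Every input the analysis consumes can be generated here: Gaussian-band
reference spectra, pH titration series mixed by the monoprotic protonation
law, transglycosylation time courses from reversible mass-action kinetics,
and HPLC peak tables proportional to species concentrations.  The kinetic
generator is thermodynamically consistent by construction — its rate laws
are parameterized by the same equilibrium constants as the equilibrium
solver, so trajectories relax to the state the solver predicts.

The rate law is deliberately generic reversible mass action rather than a
Michaelis–Menten scheme: the generator's job is thermodynamically
consistent trajectories with a known endpoint, not enzymological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import TransglySystem, solve_equilibrium
from .hplc import DEFAULT_RETENTION_TIMES, Peak, PeakTable
from .spectro import ReferenceSet, Spectrum, TitrationSeries, henderson_alpha

__all__ = [
    "BandModel",
    "KineticTrajectory",
    "SyntheticTitration",
    "make_references",
    "band_spectrum",
    "make_titration",
    "simulate_transglycosylation",
    "make_peak_table",
    "DEFAULT_BANDS",
]

SPECIES_ORDER = (
    "donor_nucleoside",
    "donor_base",
    "acceptor_base",
    "product_nucleoside",
    "pentose1P",
    "phosphate",
)

# plausible chromophore bands for a 2-selenopyrimidine titration: the
# deprotonated anion is red-shifted toward the ~307 nm maximum seen for the
# selenium species, the protonated form absorbs near 260 nm
DEFAULT_BANDS = {
    "protonated": [(262.0, 12.0, 0.80), (300.0, 18.0, 0.25)],
    "deprotonated": [(271.0, 13.0, 0.55), (307.0, 15.0, 0.85)],
}


@dataclass(frozen=True)
class BandModel:
    """Sum-of-Gaussians description of one reference state's spectrum:
    a list of (center nm, width nm, amplitude AU) bands per state."""

    states: dict

    def __post_init__(self) -> None:
        for name, bands in self.states.items():
            for center, width, amp in bands:
                if width <= 0:
                    raise ValueError(f"band width must be > 0 in state {name!r}")
                if amp < 0:
                    raise ValueError(f"band amplitude must be >= 0 in state {name!r}")


@dataclass(frozen=True)
class SyntheticTitration:
    """A generated titration series together with its ground truth."""

    series: TitrationSeries
    pka_true: float
    noise_sd: float
    seed: int

    def truth(self) -> dict:
        return {"pKa": self.pka_true, "noise_sd": self.noise_sd, "seed": self.seed}


@dataclass(frozen=True)
class KineticTrajectory:
    """Time-resolved species concentrations from a reversible mass-action
    simulation, with the generating parameters attached."""

    time: np.ndarray  # min
    concentrations: np.ndarray  # (n_times, 6), columns in SPECIES_ORDER
    system: TransglySystem
    kf1: float  # mM^-1 min^-1, donor phosphorolysis forward coefficient
    kf2: float  # mM^-1 min^-1, acceptor glycosylation forward coefficient
    equilibrated: bool

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[:, SPECIES_ORDER.index(name)]

    @property
    def conversion(self) -> np.ndarray:
        return self.species("product_nucleoside") / self.system.mix.acceptor_pool

    def state_at(self, i: int) -> dict:
        return dict(zip(SPECIES_ORDER, self.concentrations[i]))


def make_references(
    bands: BandModel | dict | None = None,
    grid: np.ndarray | None = None,
) -> ReferenceSet:
    """Reference spectra as sums of Gaussian bands on a wavelength grid.

    Defaults emulate a protonated/deprotonated 2-selenopyrimidine pair on
    the 250–350 nm grid in 1 nm steps.
    """
    if bands is None:
        bands = BandModel(DEFAULT_BANDS)
    elif isinstance(bands, dict):
        bands = BandModel(bands)
    if grid is None:
        grid = np.arange(250.0, 351.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    spectra = {
        name: band_spectrum(state_bands, grid)
        for name, state_bands in bands.states.items()
    }
    return ReferenceSet.from_spectra(**spectra)


def band_spectrum(bands, grid) -> Spectrum:
    """Sum-of-Gaussians spectrum of one state: bands are (center nm,
    width nm, amplitude AU) triples."""
    grid = np.asarray(grid, dtype=float)
    absorbance = np.zeros_like(grid)
    for center, width, amp in bands:
        if width <= 0:
            raise ValueError("band width must be > 0")
        if amp < 0:
            raise ValueError("band amplitude must be >= 0")
        absorbance += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return Spectrum(grid, absorbance)


def make_titration(
    pka_true: float,
    pH_values,
    refs: ReferenceSet,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> SyntheticTitration:
    """Generate a pH titration series mixed by the protonation law.

    spectrum(pH) = (1 - alpha) * ref_protonated + alpha * ref_deprotonated
    plus additive Gaussian noise (sd in AU), with alpha from the monoprotic
    model at ``pka_true``.  The first reference is taken as the protonated
    state, the second as the deprotonated state.
    """
    if len(refs.names) != 2:
        raise ValueError("titration generation needs exactly two references")
    ph = np.asarray(pH_values, dtype=float)
    rng = np.random.default_rng(seed)
    prot = refs.matrix[:, 0]
    deprot = refs.matrix[:, 1]
    spectra = []
    for p in ph:
        alpha = float(henderson_alpha(p, pka_true))
        clean = (1.0 - alpha) * prot + alpha * deprot
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.size)
        spectra.append(Spectrum(refs.wavelengths, noisy))
    series = TitrationSeries(pH=ph, spectra=tuple(spectra))
    return SyntheticTitration(
        series=series, pka_true=pka_true, noise_sd=noise_sd, seed=seed
    )


def simulate_transglycosylation(
    system: TransglySystem,
    kf1: float = 5.0,
    kf2: float = 5.0,
    t_grid=None,
) -> KineticTrajectory:
    """Integrate reversible mass-action kinetics of the coupled system.

    Rates (mM/min):

        r1 = kf1 * ([N_d][Pi] - [S][B_d] / K_donor)        (donor phosphorolysis)
        r2 = kf2 * ([S][B_p] - K_product * [N_p][Pi])      (acceptor glycosylation)

    Both rates vanish exactly at the equilibrium constraints, so the
    trajectory endpoint coincides with the equilibrium solver's state when
    the time horizon is long enough; ``equilibrated`` records whether both
    constraints are met within 1e-4 relative at the final time.
    """
    if kf1 <= 0 or kf2 <= 0:
        raise ValueError("rate coefficients must be > 0")
    if t_grid is None:
        t_grid = np.linspace(0.0, 60.0, 121)
    t_grid = np.asarray(t_grid, dtype=float)
    mix = system.mix
    K_d = system.constants.K_donor
    K_p = system.constants.K_product
    y0 = np.array(
        [
            mix.donor_nucleoside_0,
            mix.donor_base_0,
            mix.acceptor_base_0,
            mix.product_nucleoside_0,
            mix.pentose1P_0,
            mix.phosphate_0,
        ]
    )

    def rhs(_t, y):
        n_d, b_d, b_p, n_p, s, pi = np.maximum(y, 0.0)
        r1 = kf1 * (n_d * pi - s * b_d / K_d)
        r2 = kf2 * (s * b_p - K_p * n_p * pi)
        return [-r1, r1, -r2, r2, r1 - r2, -r1 + r2]

    sol = solve_ivp(
        rhs,
        (float(t_grid[0]), float(t_grid[-1])),
        y0,
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"kinetic integration failed: {sol.message}")
    conc = np.maximum(sol.y.T, 0.0)
    n_d, b_d, b_p, n_p, s, pi = conc[-1]
    equilibrated = False
    if min(n_d, n_p, pi) > 0 and s * b_d > 0:
        res1 = abs(s * b_d / (n_d * pi) - K_d) / K_d
        res2 = abs(s * b_p / (n_p * pi) - K_p) / K_p
        equilibrated = max(res1, res2) <= 1e-4
    return KineticTrajectory(
        time=t_grid,
        concentrations=conc,
        system=system,
        kf1=kf1,
        kf2=kf2,
        equilibrated=equilibrated,
    )


def make_peak_table(
    state: dict,
    compound_map: dict | None = None,
    response_factors: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rt_map: dict | None = None,
) -> PeakTable:
    """HPLC peak table with areas proportional to species concentrations.

    ``state`` maps species roles (SPECIES_ORDER names) or compound labels
    directly to concentrations (mM); ``compound_map`` translates roles to
    chromatogram labels (default: the 2-selenothymine / thymidine series
    {"acceptor_base": "2", "product_nucleoside": "2b", "donor_nucleoside":
    "b", "donor_base": "b''"}).  area = response_factor * concentration *
    (1 + eps) with multiplicative Gaussian noise of relative sd
    ``noise_sd``.  Species without a retention time (the sugar phosphates
    are not UV-active) and zero concentrations produce no peak.
    """
    if compound_map is None:
        compound_map = {
            "acceptor_base": "2",
            "product_nucleoside": "2b",
            "donor_nucleoside": "b",
            "donor_base": "b''",
        }
    rts = dict(DEFAULT_RETENTION_TIMES)
    if rt_map:
        rts.update(rt_map)
    factors = response_factors or {}
    rng = np.random.default_rng(seed)
    peaks = []
    for key, conc in state.items():
        label = compound_map.get(key, key)
        if label not in rts or conc <= 0:
            continue
        area = factors.get(label, 1.0) * conc
        if noise_sd > 0:
            area *= 1.0 + rng.normal(0.0, noise_sd)
        peaks.append(
            Peak(
                retention_time=rts[label],
                area=max(area, 0.0),
                compound=label,
            )
        )
    return PeakTable(peaks=tuple(peaks))
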