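"""Randomized-but-physical scenario synthesis for property testing.

Samples media, surfaces and probes from ranges that bracket and exceed
the tubulin study's regime, so every stage of the pipeline can be
exercised without external data.  Sampling is reproducible from a single
integer seed; quantities spanning decades (ionic concentration, surface
charge magnitude) are drawn log-uniformly, the rest uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .parameters import (
    ChargedSurface,
    GeometryKind,
    Medium,
    Probe,
    Scenario,
    StartRule,
    TUBULIN_MASS,
)
from .pipeline import (
    DEFAULT_HORIZON,
    SPHERE_QUOTE_TIME,
    build_paper_scenarios,
    scenario_id,
)


@dataclass(frozen=True)
class ParameterSpace:
    """Sampling ranges (inclusive bounds, reporting units where noted).

    c_s in mM, sigma in C/m^2 (negative), R and a in nm, Q_eff in units
    of e (negative), T in K, eta in Pa s.  c_s and |sigma| are sampled
    log-uniformly.
    """

    c_s_mM: tuple[float, float] = (1.0, 500.0)
    sigma: tuple[float, float] = (-0.2, -0.01)
    R_nm: tuple[float, float] = (1.0, 50.0)
    a_nm: tuple[float, float] = (1.0, 10.0)
    Q_eff_e: tuple[float, float] = (-50.0, -1.0)
    T: tuple[float, float] = (273.0, 320.0)
    eta: tuple[float, float] = (0.3e-3, 3e-3)
    epsilon_r: tuple[float, float] = (40.0, 90.0)
    d_nm: float = 0.33
    t_max: float = SPHERE_QUOTE_TIME
    Q_bare_e: float = -52.0

    def __post_init__(self) -> None:
        for name in ("c_s_mM", "R_nm", "a_nm", "T", "eta", "epsilon_r"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"range {name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        for name in ("sigma", "Q_eff_e"):
            lo, hi = getattr(self, name)
            if not lo <= hi < 0:
                raise ValueError(f"range {name} must be negative with lo <= hi, got {(lo, hi)}")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def sample_scenarios(
    space: ParameterSpace = ParameterSpace(), n: int = 10, seed: int = 0
) -> list[Scenario]:
    """Draw ``n`` valid scenarios; identical (space, n, seed) triples give
    identical lists."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    kinds = list(GeometryKind)
    rules = list(StartRule)
    c_mM = _log_uniform(rng, *space.c_s_mM, n)
    sigma = -_log_uniform(rng, -space.sigma[1], -space.sigma[0], n)
    R = units.nm_to_m(rng.uniform(*space.R_nm, n))
    a = units.nm_to_m(rng.uniform(*space.a_nm, n))
    Q_eff = units.e_to_coulomb(rng.uniform(*space.Q_eff_e, n))
    T = rng.uniform(*space.T, n)
    eta = rng.uniform(*space.eta, n)
    eps_r = rng.uniform(*space.epsilon_r, n)
    kind_idx = rng.integers(0, len(kinds), n)
    rule_idx = rng.integers(0, len(rules), n)

    scenarios = []
    for i in range(n):
        kind = kinds[kind_idx[i]]
        surface = ChargedSurface(
            kind=kind,
            R=None if kind is GeometryKind.PLANE else float(R[i]),
            d=units.nm_to_m(space.d_nm),
            sigma=float(sigma[i]),
        )
        medium = Medium(epsilon_r=float(eps_r[i]), T=float(T[i]),
                        eta=float(eta[i]), c_s=units.mM_to_si(float(c_mM[i])))
        probe = Probe(
            a=float(a[i]),
            Q_bare=units.e_to_coulomb(space.Q_bare_e),
            Q_eff=float(Q_eff[i]),
            m=TUBULIN_MASS,
        )
        scenarios.append(
            Scenario(
                surface=surface,
                medium=medium,
                probe=probe,
                start_rule=rules[rule_idx[i]],
                t_max=space.t_max,
                scenario_id=f"synthetic_{i:04d}",
            )
        )
    return scenarios


@dataclass(frozen=True)
class PaperExpectation:
    """A printed headline value for one canonical scenario.

    ``ez_nm``/``ez_time`` pin the EZ size at a stated time (relative
    tolerance ``ez_rtol``); ``debye_nm`` pins the medium's screening
    length.  Fields are None where the study quotes no number.
    """

    scenario: Scenario
    debye_nm: float
    ez_nm: float | None = None
    ez_time: float | None = None
    ez_rtol: float = 0.2


def paper_regression_fixtures() -> list[PaperExpectation]:
    """The twelve canonical scenarios paired with the quoted checks:
    EZ ~ 30 nm for the microtubule at 10 mM, ~ 20 nm at 10 us for the
    tubulin sphere at 10 mM (both start rules: the curves nearly
    coincide), and the Debye lengths 3 nm (10 mM) / 0.75 nm (160 mM)."""
    fixtures = []
    for sc in build_paper_scenarios():
        c_mM = units.si_to_mM(sc.medium.c_s)
        debye_nm = 3.0 if c_mM == 10.0 else 0.75
        ez_nm = ez_time = None
        if c_mM == 10.0:
            if sc.surface.kind is GeometryKind.CYLINDER:
                ez_nm, ez_time = 30.0, DEFAULT_HORIZON
            elif sc.surface.kind is GeometryKind.SPHERE:
                ez_nm, ez_time = 20.0, SPHERE_QUOTE_TIME
        fixtures.append(
            PaperExpectation(
                scenario=sc, debye_nm=debye_nm, ez_nm=ez_nm, ez_time=ez_time
            )
        )
    return fixtures


def synthesis_config(space: ParameterSpace = ParameterSpace(), n: int = 10,
                     seed: int = 0) -> dict:
    """Emit a pipeline-consumable config for ``n`` sampled scenarios."""
    entries = []
    for sc in sample_scenarios(space, n, seed):
        entry = {
            "id": sc.scenario_id,
            "geometry": sc.surface.kind.value,
            "concentration_mM": units.si_to_mM(sc.medium.c_s),
            "start_rule": sc.start_rule.value,
            "horizon_us": units.s_to_us(sc.t_max),
            "d_nm": units.m_to_nm(sc.surface.d),
            "sigma_C_per_m2": sc.surface.sigma,
            "a_nm": units.m_to_nm(sc.probe.a),
            "Q_bare_e": units.coulomb_to_e(sc.probe.Q_bare),
            "Q_eff_e": units.coulomb_to_e(sc.probe.Q_eff),
            "mass_kDa": sc.probe.m / units.kda_to_kg(1.0),
            "epsilon_r": sc.medium.epsilon_r,
            "T_K": sc.medium.T,
            "eta_Pa_s": sc.medium.eta,
        }
        if sc.surface.R is not None:
            entry["R_nm"] = units.m_to_nm(sc.surface.R)
        entries.append(entry)
    return {
        "seed": seed,
        "solver": {"mode": "overdamped", "rtol": 1e-8},
        "scenarios": entries,
    }
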