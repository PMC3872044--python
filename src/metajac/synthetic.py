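"""Toy kinetic models with known steady states and analytic Jacobians.

The generator builds compartmented mass-action networks, locates a strictly
positive steady state, evaluates the analytic Jacobian J = N dr/dM there,
and draws biological replicates as independent samples from the stationary
distribution of the linearized (Ornstein--Uhlenbeck) fluctuation process:
mean x*, covariance solving J C + C J^T = -2 D_true.  Because the ground
truth (J, C, D) is known exactly, every stage of the inverse workflow can be
validated without external data.

Presets
-------
``chain3``
    three-pool linear chain in one compartment (influx, two conversions,
    efflux); closed-form steady state.
``carb13``
    thirteen carbohydrate pools across cytosol / plastid / vacuole
    (sucrose, raffinose, glucose, fructose in cytosol and vacuole; sucrose,
    raffinose, glucose, fructose, starch in the plastid) with tonoplast and
    envelope transport, sucrose synthesis/cleavage and starch turnover,
    emulating subcellular carbohydrate compartmentation in cold-treated
    Arabidopsis leaves.
``random``
    seeded random sparse stable five-pool first-order network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .inference import FluctuationMatrix, JacobianMatrix, MetaboliteDataset
from .network import MetabolicNetwork, Reaction, Species, write_sbml


class ModelError(ValueError):
    """Invalid kinetic model or simulation request."""


@dataclass(frozen=True)
class MassActionReaction:
    """One elementary mass-action step.

    ``substrates`` maps pool id -> kinetic order (and consumed coefficient),
    ``products`` maps pool id -> produced coefficient.  An empty substrate
    map is a constant (zeroth-order) influx with rate ``rate_constant``.
    Units: 1/time for first order, 1/(conc * time) for second order.
    """

    id: str
    substrates: dict
    products: dict
    rate_constant: float


@dataclass
class KineticModel:
    pools: list
    pool_compartments: dict
    reactions: list

    def __post_init__(self) -> None:
        for r in self.reactions:
            if r.rate_constant <= 0:
                raise ModelError(f"rate constant of {r.id!r} must be positive")
            for sid in list(r.substrates) + list(r.products):
                if sid not in self.pools:
                    raise ModelError(f"reaction {r.id!r} references unknown pool {sid!r}")

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def stoichiometric_matrix(self) -> np.ndarray:
        idx = {p: i for i, p in enumerate(self.pools)}
        N = np.zeros((self.n_pools, len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sid, order in r.substrates.items():
                N[idx[sid], j] -= order
            for sid, coef in r.products.items():
                N[idx[sid], j] += coef
        return N

    def rates(self, x: np.ndarray) -> np.ndarray:
        idx = {p: i for i, p in enumerate(self.pools)}
        r = np.empty(len(self.reactions))
        for j, rx in enumerate(self.reactions):
            v = rx.rate_constant
            for sid, order in rx.substrates.items():
                v *= x[idx[sid]] ** order
            r[j] = v
        return r

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """dM/dt = N r(M)."""
        return self.stoichiometric_matrix() @ self.rates(x)

    def rate_jacobian(self, x: np.ndarray) -> np.ndarray:
        """dr/dM: partial derivatives of every mass-action rate."""
        idx = {p: i for i, p in enumerate(self.pools)}
        dr = np.zeros((len(self.reactions), self.n_pools))
        for j, rx in enumerate(self.reactions):
            for sid, order in rx.substrates.items():
                v = rx.rate_constant * order * x[idx[sid]] ** (order - 1)
                for other, o2 in rx.substrates.items():
                    if other != sid:
                        v *= x[idx[other]] ** o2
                dr[j, idx[sid]] = v
        return dr

    def is_linear(self) -> bool:
        return all(
            sum(r.substrates.values()) <= 1 and all(o == 1 for o in r.substrates.values())
            for r in self.reactions
        )

    def to_network(self) -> MetabolicNetwork:
        """The model's topology as a :class:`MetabolicNetwork` (SBML-exportable)."""
        species = [
            Species(id=p, name=p, compartment=self.pool_compartments[p])
            for p in self.pools
        ]
        reactions = []
        for r in self.reactions:
            stoich: dict = {}
            for sid, order in r.substrates.items():
                stoich[sid] = stoich.get(sid, 0.0) - order
            for sid, coef in r.products.items():
                stoich[sid] = stoich.get(sid, 0.0) + coef
            if stoich:
                reactions.append(Reaction(id=r.id, reversible=False, stoichiometry=stoich))
        compartments = sorted(set(self.pool_compartments.values()))
        return MetabolicNetwork(species=species, reactions=reactions, compartments=compartments)

    def to_sbml(self) -> str:
        return write_sbml(self.to_network())


@dataclass
class SimulationResult:
    model: KineticModel
    steady_state: np.ndarray
    true_jacobian: JacobianMatrix
    true_covariance: np.ndarray
    d_true: FluctuationMatrix
    replicates: MetaboliteDataset
    noise_scale: float
    #: number of sample cells truncated at the positivity floor
    n_truncated: int = 0


def find_steady_state(model: KineticModel, tol: float = 1e-10) -> np.ndarray:
    """Strictly positive steady state of the mass-action ODE system.

    Purely first-order systems are solved exactly as a linear system;
    otherwise a root finder is started from several positive initial
    guesses.  The residual ``||dM/dt||_inf`` must fall below ``tol`` times
    the flux scale.
    """
    n = model.n_pools
    N = model.stoichiometric_matrix()
    if model.is_linear():
        idx = {p: i for i, p in enumerate(model.pools)}
        A = np.zeros((n, n))
        c = np.zeros(n)
        for j, r in enumerate(model.reactions):
            if r.substrates:
                (sid, _), = r.substrates.items()
                A[:, idx[sid]] += N[:, j] * r.rate_constant
            else:
                c += N[:, j] * r.rate_constant
        try:
            x = np.linalg.solve(A, -c)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"no unique steady state: {exc}") from exc
        candidates = [x]
    else:
        candidates = []
        for scale in (1.0, 0.5, 2.0, 5.0, 0.2):
            sol = scipy.optimize.root(model.rhs, np.full(n, scale), method="hybr")
            if sol.success:
                candidates.append(sol.x)

    flux_scale = 1.0
    for x in candidates:
        if np.all(x > 0):
            flux_scale = max(np.max(np.abs(model.rates(x))), 1.0)
            if np.max(np.abs(model.rhs(x))) <= tol * flux_scale:
                return x
    raise ModelError("no strictly positive steady state found")


def analytic_jacobian(model: KineticModel, state: np.ndarray) -> JacobianMatrix:
    """J = N dr/dM evaluated at a strictly positive state.

    The structure mask is the nonzero pattern implied by the rate laws
    (which entries *can* be nonzero for some positive state), so that
    coincidental numerical cancellations do not shrink the mask.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state <= 0):
        raise ModelError("state must be strictly positive")
    N = model.stoichiometric_matrix()
    J = N @ model.rate_jacobian(state)
    # structural pattern: evaluate dr/dM symbolically-by-pattern at all-ones
    pattern = (np.abs(N) @ (model.rate_jacobian(np.ones(model.n_pools)) != 0.0)) > 0
    return JacobianMatrix(
        pool_ids=list(model.pools),
        values=np.where(pattern, J, 0.0),
        structure_mask=pattern,
    )


def _assert_stable(J: np.ndarray, context: str) -> None:
    w = np.linalg.eigvals(J)
    if w.real.max() >= 0:
        raise ModelError(f"{context}: Jacobian is not Hurwitz-stable (max Re = {w.real.max():g})")


def _chain3() -> KineticModel:
    pools = ["met_a_cytosol", "met_b_cytosol", "met_c_cytosol"]
    reactions = [
        MassActionReaction("influx_a", {}, {"met_a_cytosol": 1.0}, 1.0),
        MassActionReaction("conv_ab", {"met_a_cytosol": 1}, {"met_b_cytosol": 1.0}, 0.8),
        MassActionReaction("conv_bc", {"met_b_cytosol": 1}, {"met_c_cytosol": 1.0}, 0.5),
        MassActionReaction("efflux_c", {"met_c_cytosol": 1}, {}, 1.2),
    ]
    return KineticModel(
        pools=pools,
        pool_compartments={p: "cytosol" for p in pools},
        reactions=reactions,
    )


#: default rate constants of the carb13 preset (order-1 values; the slowest
#: eigenvalue of the resulting Jacobian stays above 0.05 in magnitude)
CARB13_RATES = {
    "influx_glc_cyt": 1.0,
    "influx_frc_cyt": 1.0,
    "sucrose_synthesis_cyt": 0.5,
    "invertase_cyt": 0.5,
    "glycolysis_glc_cyt": 0.3,
    "glycolysis_frc_cyt": 0.3,
    "raffinose_synthesis_cyt": 0.4,
    "tonoplast_suc_in": 0.6,
    "tonoplast_raf_in": 0.5,
    "tonoplast_glc_out": 0.7,
    "tonoplast_frc_out": 0.7,
    "invertase_vac": 0.8,
    "raffinose_turnover_vac": 0.6,
    "envelope_suc_in": 0.6,
    "envelope_raf_in": 0.3,
    "envelope_glc_out": 0.7,
    "envelope_frc_out": 0.7,
    "invertase_pla": 0.8,
    "starch_synthesis": 0.9,
    "starch_degradation": 0.4,
    "raffinose_turnover_pla": 0.6,
}


def _carb13(rates: dict | None = None) -> KineticModel:
    k = dict(CARB13_RATES)
    if rates:
        unknown = set(rates) - set(k)
        if unknown:
            raise ModelError(f"unknown carb13 rate constants: {sorted(unknown)}")
        k.update(rates)
    suc_c, raf_c = "sucrose_cytosol", "raffinose_cytosol"
    glc_c, frc_c = "glucose_cytosol", "fructose_cytosol"
    suc_v, raf_v = "sucrose_vacuole", "raffinose_vacuole"
    glc_v, frc_v = "glucose_vacuole", "fructose_vacuole"
    suc_p, raf_p = "sucrose_plastid", "raffinose_plastid"
    glc_p, frc_p, sta_p = "glucose_plastid", "fructose_plastid", "starch_plastid"
    pools = [
        suc_c, raf_c, glc_c, frc_c,
        suc_v, raf_v, glc_v, frc_v,
        suc_p, raf_p, glc_p, frc_p, sta_p,
    ]
    comp = {}
    for p in pools:
        comp[p] = p.rsplit("_", 1)[1]
    R = MassActionReaction
    reactions = [
        R("influx_glc_cyt", {}, {glc_c: 1.0}, k["influx_glc_cyt"]),
        R("influx_frc_cyt", {}, {frc_c: 1.0}, k["influx_frc_cyt"]),
        R("sucrose_synthesis_cyt", {glc_c: 1, frc_c: 1}, {suc_c: 1.0}, k["sucrose_synthesis_cyt"]),
        R("invertase_cyt", {suc_c: 1}, {glc_c: 1.0, frc_c: 1.0}, k["invertase_cyt"]),
        R("glycolysis_glc_cyt", {glc_c: 1}, {}, k["glycolysis_glc_cyt"]),
        R("glycolysis_frc_cyt", {frc_c: 1}, {}, k["glycolysis_frc_cyt"]),
        R("raffinose_synthesis_cyt", {suc_c: 1}, {raf_c: 1.0}, k["raffinose_synthesis_cyt"]),
        R("tonoplast_suc_in", {suc_c: 1}, {suc_v: 1.0}, k["tonoplast_suc_in"]),
        R("tonoplast_raf_in", {raf_c: 1}, {raf_v: 1.0}, k["tonoplast_raf_in"]),
        R("tonoplast_glc_out", {glc_v: 1}, {glc_c: 1.0}, k["tonoplast_glc_out"]),
        R("tonoplast_frc_out", {frc_v: 1}, {frc_c: 1.0}, k["tonoplast_frc_out"]),
        R("invertase_vac", {suc_v: 1}, {glc_v: 1.0, frc_v: 1.0}, k["invertase_vac"]),
        R("raffinose_turnover_vac", {raf_v: 1}, {}, k["raffinose_turnover_vac"]),
        R("envelope_suc_in", {suc_c: 1}, {suc_p: 1.0}, k["envelope_suc_in"]),
        R("envelope_raf_in", {raf_c: 1}, {raf_p: 1.0}, k["envelope_raf_in"]),
        R("envelope_glc_out", {glc_p: 1}, {glc_c: 1.0}, k["envelope_glc_out"]),
        R("envelope_frc_out", {frc_p: 1}, {frc_c: 1.0}, k["envelope_frc_out"]),
        R("invertase_pla", {suc_p: 1}, {glc_p: 1.0, frc_p: 1.0}, k["invertase_pla"]),
        R("starch_synthesis", {glc_p: 1}, {sta_p: 1.0}, k["starch_synthesis"]),
        R("starch_degradation", {sta_p: 1}, {glc_p: 1.0}, k["starch_degradation"]),
        R("raffinose_turnover_pla", {raf_p: 1}, {}, k["raffinose_turnover_pla"]),
    ]
    return KineticModel(pools=pools, pool_compartments=comp, reactions=reactions)


def _random_model(rng: np.random.Generator, n_pools: int = 5) -> KineticModel:
    pools = [f"met_{chr(ord('a') + i)}_cytosol" for i in range(n_pools)]
    reactions = [MassActionReaction("influx", {}, {pools[0]: 1.0}, float(rng.uniform(0.5, 1.5)))]
    # chain backbone guarantees connectivity; every pool gets its own efflux,
    # which makes the (compartmental) first-order system strictly stable
    for i in range(n_pools - 1):
        reactions.append(
            MassActionReaction(
                f"conv_{i}_{i + 1}", {pools[i]: 1}, {pools[i + 1]: 1.0},
                float(rng.uniform(0.3, 1.5)),
            )
        )
    n_extra = int(rng.integers(1, 4))
    for e in range(n_extra):
        i, j = rng.choice(n_pools, size=2, replace=False)
        reactions.append(
            MassActionReaction(
                f"extra_{e}_{i}_{j}", {pools[int(i)]: 1}, {pools[int(j)]: 1.0},
                float(rng.uniform(0.3, 1.5)),
            )
        )
    for i in range(n_pools):
        reactions.append(
            MassActionReaction(
                f"efflux_{i}", {pools[i]: 1}, {}, float(rng.uniform(0.1, 0.5))
            )
        )
    return KineticModel(
        pools=pools, pool_compartments={p: "cytosol" for p in pools}, reactions=reactions
    )


def build_toy_network(preset: str, rng_seed: int = 0, rates: dict | None = None) -> KineticModel:
    """Build a preset toy kinetic model with a verified stable steady state.

    ``rates`` overrides named rate constants (carb13 only), e.g. to double a
    single transport step when constructing a perturbed condition.
    """
    if preset == "chain3":
        model = _chain3()
    elif preset == "carb13":
        model = _carb13(rates)
    elif preset == "random":
        ss = np.random.SeedSequence(rng_seed)
        model = None
        for child in ss.spawn(100):
            candidate = _random_model(np.random.default_rng(child))
            try:
                x = find_steady_state(candidate)
                _assert_stable(analytic_jacobian(candidate, x).values, preset)
            except ModelError:
                continue
            model = candidate
            break
        if model is None:
            raise ModelError("no stable random model found in 100 attempts")
        return model
    else:
        raise ModelError(f"unknown preset {preset!r}")
    x = find_steady_state(model)
    _assert_stable(analytic_jacobian(model, x).values, preset)
    return model


def simulate_replicates(
    model: KineticModel,
    n_replicates: int,
    noise_scale: float = 0.05,
    rng_seed: int = 0,
    condition_label: str = "",
) -> SimulationResult:
    """Draw replicates from the stationary fluctuation distribution.

    Replicates are independent samples of the stationary Gaussian of the
    linearized dynamics: mean x*, covariance C_true solving
    J C + C J^T = -2 D_true with D_true = (noise_scale^2 / 2) diag(x*)
    (concentration-scaled intrinsic noise).  Sampling is exact -- no
    time-stepping error.  Negative draws are truncated at 1e-9 x* and
    counted in ``n_truncated``.
    """
    if n_replicates < 2:
        raise ModelError("need at least 2 replicates")
    if noise_scale < 0:
        raise ModelError("noise_scale must be non-negative")
    x = find_steady_state(model)
    Jm = analytic_jacobian(model, x)
    _assert_stable(Jm.values, "simulate_replicates")
    d_diag = (noise_scale**2 / 2.0) * x
    if noise_scale == 0.0:
        C_true = np.zeros((model.n_pools, model.n_pools))
        draws = np.tile(x, (n_replicates, 1))
        n_trunc = 0
    else:
        C_true = scipy.linalg.solve_continuous_lyapunov(Jm.values, -2.0 * np.diag(d_diag))
        C_true = (C_true + C_true.T) / 2.0
        rng = np.random.default_rng(np.random.SeedSequence(rng_seed))
        draws = rng.multivariate_normal(x, C_true, size=n_replicates, method="svd")
        floor = 1e-9 * x
        below = draws < floor[None, :]
        n_trunc = int(below.sum())
        draws = np.where(below, floor[None, :], draws)
    dataset = MetaboliteDataset(
        pool_ids=list(model.pools), values=draws, condition_label=condition_label
    )
    return SimulationResult(
        model=model,
        steady_state=x,
        true_jacobian=Jm,
        true_covariance=C_true,
        d_true=FluctuationMatrix(diagonal=d_diag),
        replicates=dataset,
        noise_scale=noise_scale,
        n_truncated=n_trunc,
    )
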