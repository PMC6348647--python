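"""LP-based blocked-reaction and blocked-species detection.

Three checking modes are offered:

* **FBA mode** — a reaction is blocked when it cannot carry a steady-state
  flux of at least the activation threshold ε in either permitted direction;
  a species is blocked when every reaction able to generate it is blocked.
* **Bi-directional mode** — the same check after relaxing every reaction to
  full reversibility, which isolates inactivity caused by over-constrained
  or misdirected reactions rather than by missing network structure.
* **Dynamic mode** — a species-level producibility check under growth: a
  species is active when the network can continuously drain (dilute) it
  while the biomass reaction carries a minimum flux δ.  One LP decides all
  species at once.

Two FBA-mode implementations exist: a per-reaction flux-variability oracle
(:func:`blocked_oracle`) and an LP-frugal batched algorithm
(:func:`check_fba`) that certifies the support of a few batched activation
LPs and falls back to individual confirmation only for stubborn reversible
reactions.  The two must agree exactly; the batched algorithm only saves
optimisation rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core_model import Model, stoichiometric_matrix

__all__ = [
    "ConsistencyConfig",
    "ConsistencyResult",
    "SolverError",
    "blocked_oracle",
    "check_fba",
    "check_bidirectional",
    "check_dynamic",
    "dynamic_species_oracle",
    "species_status",
    "batched_activation_lp",
]

ACTIVE = "active"
BLOCKED = "blocked"


class SolverError(RuntimeError):
    """The LP solver returned a status other than optimal/infeasible."""


@dataclass(frozen=True)
class ConsistencyConfig:
    """Numeric parameters of the consistency checks.

    eps
        activation threshold ε in flux units: a reaction counts as active
        when it can carry |v| ≥ 0.99·ε (the 1% margin absorbs solver
        round-off).  1e-4 is the customary FastCC-family threshold.
    zero_tol
        numerical zero ζ used when reading LP solutions.
    delta_growth
        minimum biomass flux δ enforced in dynamic mode.
    big_M
        bound magnitude used when relaxing reactions (bi-directional mode,
        open exchanges).
    open_exchanges
        when set, every import/export reaction's bounds are opened to
        [0, M] (or [−M, M] if reversible) before checking.
    seed
        seed for the randomized orientation of reversible candidates in the
        batched algorithm; results are deterministic per seed.
    max_batch_rounds
        cap on batched LP rounds before unresolved reversible reactions are
        confirmed individually in both directions.
    """

    eps: float = 1e-4
    zero_tol: float = 1e-9
    delta_growth: float = 1e-4
    big_M: float = 1000.0
    open_exchanges: bool = False
    seed: int = 0
    max_batch_rounds: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.zero_tol < self.eps):
            raise ValueError("require 0 < zero_tol < eps")
        if self.delta_growth <= 0:
            raise ValueError("delta_growth must be positive")
        if self.big_M < self.eps:
            raise ValueError("big_M must be at least eps")


@dataclass
class ConsistencyResult:
    """Blocked/active classification of a model under one checking mode."""

    mode: str
    reaction_status: Dict[str, str]
    species_status: Dict[str, str]
    lp_count: int
    config: ConsistencyConfig
    warnings: List[str] = field(default_factory=list)

    @property
    def blocked_reactions(self) -> set:
        return {r for r, s in self.reaction_status.items() if s == BLOCKED}

    @property
    def blocked_species(self) -> set:
        return {s for s, st in self.species_status.items() if st == BLOCKED}

    @property
    def blocked_nodes(self) -> set:
        return self.blocked_reactions | self.blocked_species

    def status_of(self, node_id: str) -> str:
        if node_id in self.reaction_status:
            return self.reaction_status[node_id]
        return self.species_status[node_id]

    def to_tsv(self) -> str:
        rows = ["id\tkind\tstatus\tmode"]
        for rid, st in self.reaction_status.items():
            rows.append(f"{rid}\treaction\t{st}\t{self.mode}")
        for sid, st in self.species_status.items():
            rows.append(f"{sid}\tspecies\t{st}\t{self.mode}")
        return "\n".join(rows) + "\n"

    def sidecar(self) -> dict:
        cfg = self.config
        return {
            "mode": self.mode,
            "lp_count": self.lp_count,
            "warnings": list(self.warnings),
            "config": {
                "eps": cfg.eps,
                "zero_tol": cfg.zero_tol,
                "delta_growth": cfg.delta_growth,
                "big_M": cfg.big_M,
                "open_exchanges": cfg.open_exchanges,
                "seed": cfg.seed,
                "max_batch_rounds": cfg.max_batch_rounds,
            },
        }


# ---------------------------------------------------------------------------
# LP plumbing
# ---------------------------------------------------------------------------


def _prepared(model: Model, cfg: ConsistencyConfig):
    """S, bounds arrays and id orderings, with open-exchange preprocessing."""
    S, row_index, col_index = stoichiometric_matrix(model)
    rids = list(col_index)
    lb = np.array([model.reactions[r].lb for r in rids], dtype=float)
    ub = np.array([model.reactions[r].ub for r in rids], dtype=float)
    if cfg.open_exchanges:
        for j, rid in enumerate(rids):
            rx = model.reactions[rid]
            non_boundary = [s for s in rx.stoich if not model.species[s].boundary]
            has_react = any(rx.stoich[s] < 0 for s in non_boundary)
            has_prod = any(rx.stoich[s] > 0 for s in non_boundary)
            if not (has_react and has_prod):  # exchange with the environment
                lb[j] = -cfg.big_M if lb[j] < 0 else 0.0
                ub[j] = cfg.big_M
    return S, row_index, rids, lb, ub


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds, what: str):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 2:  # infeasible
        return None
    if res.status != 0:
        raise SolverError(f"LP for {what} ended with solver status {res.status}: "
                          f"{res.message}")
    return res


# ---------------------------------------------------------------------------
# Species classification from reaction statuses
# ---------------------------------------------------------------------------


def species_status(model: Model, reaction_status: Dict[str, str]) -> Dict[str, str]:
    """Classify species from reaction statuses.

    A reaction *can generate* species s when it produces s with forward flux
    allowed (coefficient > 0 and ub > 0) or consumes s but may run backwards
    (coefficient < 0 and lb < 0).  A species is blocked when every reaction
    able to generate it is blocked — vacuously so when nothing can.
    Boundary species are exempt from classification.
    """
    status: Dict[str, str] = {}
    generators: Dict[str, list] = {s.id: [] for s in model.species.values() if not s.boundary}
    for rx in model.reactions.values():
        for sid, coef in rx.stoich.items():
            if sid not in generators:
                continue
            if (coef > 0 and rx.ub > 0) or (coef < 0 and rx.lb < 0):
                generators[sid].append(rx.id)
    for sid, gens in generators.items():
        alive = any(reaction_status[r] == ACTIVE for r in gens)
        status[sid] = ACTIVE if alive else BLOCKED
    return status


# ---------------------------------------------------------------------------
# Brute-force oracle (per-reaction flux variability)
# ---------------------------------------------------------------------------


def blocked_oracle(model: Model, cfg: Optional[ConsistencyConfig] = None) -> ConsistencyResult:
    """Per-reaction flux-variability classification (the reference method).

    For each reaction, maximize its flux subject to S·v = 0 and the bounds;
    if the optimum falls short of 0.99·ε and the reaction may run backwards,
    minimize it as well.  Exact but expensive: up to one LP per irreversible
    and two per reversible reaction.
    """
    cfg = cfg or ConsistencyConfig()
    if not model.reactions:
        raise ValueError("model has no reactions")
    S, _, rids, lb, ub = _prepared(model, cfg)
    n = len(rids)
    A_eq = S
    b_eq = np.zeros(S.shape[0])
    bounds = list(zip(lb, ub))
    thr = 0.99 * cfg.eps

    status: Dict[str, str] = {}
    lp_count = 0
    for j, rid in enumerate(rids):
        c = np.zeros(n)
        c[j] = -1.0  # maximize v_j
        res = _solve(c, None, None, A_eq, b_eq, bounds, f"reaction {rid}")
        lp_count += 1
        if res is None:
            raise SolverError(f"steady-state LP infeasible for reaction {rid}")
        if -res.fun >= thr:
            status[rid] = ACTIVE
            continue
        if lb[j] < 0:
            c[j] = 1.0  # minimize v_j
            res = _solve(c, None, None, A_eq, b_eq, bounds, f"reaction {rid}")
            lp_count += 1
            if res is not None and res.fun <= -thr:
                status[rid] = ACTIVE
                continue
        status[rid] = BLOCKED

    return ConsistencyResult(
        mode="fba",
        reaction_status=status,
        species_status=species_status(model, status),
        lp_count=lp_count,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Batched activation LP
# ---------------------------------------------------------------------------


def batched_activation_lp(
    model: Model,
    candidates: Sequence[Tuple[str, int]],
    cfg: Optional[ConsistencyConfig] = None,
):
    """Solve one activation LP over a set of oriented candidate reactions.

    Variables are the flux vector v plus one auxiliary weight w_j per
    candidate (reaction id, orientation σ ∈ {+1, −1}); the LP maximizes
    Σ w_j subject to S·v = 0, the flux bounds, 0 ≤ w_j ≤ ε and
    w_j ≤ σ_j·v_j.  Orientation +1 requires ub > 0, −1 requires lb < 0.
    Returns ``(flux, weights)`` as id-keyed dicts (weights keyed by
    candidate reaction id).
    """
    cfg = cfg or ConsistencyConfig()
    if not candidates:
        raise ValueError("candidates must be non-empty")
    S, _, rids, lb, ub = _prepared(model, cfg)
    col = {r: j for j, r in enumerate(rids)}
    for rid, sig in candidates:
        if sig == 1 and ub[col[rid]] <= 0:
            raise ValueError(f"orientation +1 invalid for {rid} (ub <= 0)")
        if sig == -1 and lb[col[rid]] >= 0:
            raise ValueError(f"orientation -1 invalid for {rid} (lb >= 0)")
        if sig not in (1, -1):
            raise ValueError("orientation must be +1 or -1")
    v, w, _ = _activation_lp(S, lb, ub, [(col[r], s) for r, s in candidates], cfg)
    flux = {rid: v[j] for j, rid in enumerate(rids)}
    weights = {rid: w[k] for k, (rid, _) in enumerate(candidates)}
    return flux, weights


def _activation_lp(S, lb, ub, cand: Sequence[Tuple[int, int]], cfg: ConsistencyConfig):
    """Internal index-based version; ``cand`` is (column, σ) pairs.

    Note that w_j ≥ 0 together with w_j ≤ σ_j·v_j pins the sign of every
    candidate's flux, so batching reversible reactions restricts the
    polytope — the reason the FBA check batches irreversible reactions
    (whose sign constraint is vacuous) separately from reversible ones.
    """
    n = S.shape[1]
    k = len(cand)
    m = S.shape[0]
    # variables: v (n) then w (k)
    A_eq = sparse.hstack([S, sparse.csr_matrix((m, k))], format="csr") if k else S
    b_eq = np.zeros(m)
    # w_j - sigma_j * v_j <= 0
    rows, cols, vals = [], [], []
    for i, (j, sig) in enumerate(cand):
        rows += [i, i]
        cols += [n + i, j]
        vals += [1.0, -float(sig)]
    A_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(k, n + k))
    b_ub = np.zeros(k)
    bounds = list(zip(lb, ub)) + [(0.0, cfg.eps)] * k
    c = np.zeros(n + k)
    c[n:] = -1.0
    res = _solve(c, A_ub, b_ub, A_eq, b_eq, bounds, "batched activation")
    if res is None:  # v = 0, w = 0 is always feasible
        raise SolverError("activation LP reported infeasible (should not happen)")
    v = res.x[:n]
    w = res.x[n:]
    return v, w, res


# ---------------------------------------------------------------------------
# LP-frugal FBA-mode check
# ---------------------------------------------------------------------------


def check_fba(model: Model, cfg: Optional[ConsistencyConfig] = None) -> ConsistencyResult:
    """Batched FBA-mode consistency check, exact but LP-frugal.

    Round 1 solves one activation LP over all irreversible reactions; the
    support of the solution (|v| ≥ 0.99·ε, any reaction) certifies activity,
    and irreversible candidates left at zero are declared blocked — their
    activation certificates superpose without sign cancellation, so the one
    batch decides them.  Unresolved reversible reactions then go through
    batched rounds in seeded random orientations (flipped when a round
    stagnates); batching continues only while it keeps paying for itself in
    saved LPs, after which survivors are confirmed individually in both
    directions, still harvesting the support of every LP solved.  The
    classification always equals :func:`blocked_oracle`; only the LP count
    differs.
    """
    cfg = cfg or ConsistencyConfig()
    if not model.reactions:
        raise ValueError("model has no reactions")
    S, _, rids, lb, ub = _prepared(model, cfg)
    n = len(rids)
    A_eq = S
    b_eq = np.zeros(S.shape[0])
    bounds = list(zip(lb, ub))
    thr = 0.99 * cfg.eps
    rng = np.random.default_rng(cfg.seed)

    status: Dict[str, str] = {}
    # reactions that cannot reach the threshold in either direction are
    # blocked without any LP
    testable = []
    for j, rid in enumerate(rids):
        if ub[j] < thr and lb[j] > -thr:
            status[rid] = BLOCKED
        else:
            testable.append(j)

    lp_count = 0
    irrev = [j for j in testable if lb[j] >= 0]
    rev = [j for j in testable if lb[j] < 0]

    def mark_support(v: np.ndarray) -> int:
        newly = 0
        for j in testable:
            rid = rids[j]
            if rid not in status and abs(v[j]) >= thr:
                status[rid] = ACTIVE
                newly += 1
        return newly

    def orient(j: int) -> int:
        if ub[j] < thr:  # only the backward direction can reach eps
            return -1
        if lb[j] > -thr:
            return 1
        return 1 if rng.integers(2) else -1

    # ---- round 1: every testable irreversible reaction in one batch ---------
    # The activation constraint w_j ≤ σ_j·v_j with w_j ≥ 0 pins sign(v_j) for
    # every candidate, which is vacuous for irreversible reactions (lb ≥ 0
    # already) — so one batch decides them all: actives by support,
    # the rest blocked (their certificates superpose without cancellation).
    # Reversible reactions certified in passing by the support count as
    # batch-resolved; they bankroll the reversible rounds below.
    resolved_rev = 0

    def count_unresolved_rev() -> int:
        return sum(1 for j in rev if rids[j] not in status)

    if irrev:
        rev_before = count_unresolved_rev()
        v, _, _ = _activation_lp(S, lb, ub, [(j, 1) for j in irrev], cfg)
        lp_count += 1
        mark_support(v)
        for j in irrev:
            rid = rids[j]
            if rid not in status:
                status[rid] = BLOCKED
        resolved_rev += rev_before - count_unresolved_rev()

    # ---- batched rounds for reversible candidates ----------------------------
    # Batching a reversible candidate pins its flux sign for the round, so a
    # batch can only certify activity (by support), never blockedness.  Each
    # already-certified reversible saved at least one individual LP, and each
    # round costs one: rounds are allowed only while they stay fully paid
    # for, which keeps lp_count within both 1 + 2·(#reversible) and the
    # per-reaction oracle count.  Stagnant rounds flip every unresolved
    # orientation before the next attempt.
    sigma = {j: orient(j) for j in rev}
    batch_rounds = 0
    while irrev:
        unresolved = [j for j in rev if rids[j] not in status]
        if not unresolved:
            break
        if batch_rounds >= cfg.max_batch_rounds or batch_rounds + 1 > resolved_rev:
            break
        v, _, _ = _activation_lp(S, lb, ub, [(j, sigma[j]) for j in unresolved], cfg)
        lp_count += 1
        batch_rounds += 1
        newly = mark_support(v)
        resolved_rev += newly
        if newly == 0:  # stagnant: flip every unresolved orientation
            for j in unresolved:
                if sigma[j] == 1 and lb[j] <= -thr:
                    sigma[j] = -1
                elif sigma[j] == -1 and ub[j] >= thr:
                    sigma[j] = 1

    # ---- individual confirmation of survivors --------------------------------
    for j in sorted(rev):
        rid = rids[j]
        if rid in status:
            continue
        decided = False
        if ub[j] >= thr:
            c = np.zeros(n)
            c[j] = -1.0
            res = _solve(c, None, None, A_eq, b_eq, bounds, f"reaction {rid}")
            lp_count += 1
            mark_support(res.x)
            if -res.fun >= thr:
                status[rid] = ACTIVE
                decided = True
        if not decided and lb[j] <= -thr:
            c = np.zeros(n)
            c[j] = 1.0
            res = _solve(c, None, None, A_eq, b_eq, bounds, f"reaction {rid}")
            lp_count += 1
            mark_support(res.x)
            if res.fun <= -thr:
                status[rid] = ACTIVE
                decided = True
        if not decided:
            status[rid] = BLOCKED

    # degenerate but non-empty model with nothing testable: one trivial
    # feasibility LP keeps the accounting honest (lp_count >= 1)
    if lp_count == 0:
        _solve(np.zeros(n), None, None, A_eq, b_eq, bounds, "feasibility")
        lp_count = 1

    return ConsistencyResult(
        mode="fba",
        reaction_status=status,
        species_status=species_status(model, status),
        lp_count=lp_count,
        config=cfg,
    )


def check_bidirectional(model: Model, cfg: Optional[ConsistencyConfig] = None) -> ConsistencyResult:
    """FBA-mode check on the fully reversibilized model.

    Every reaction's bounds are relaxed to [−M, +M] before checking; the
    input model is untouched.  Whatever stays blocked here cannot be healed
    by any choice of reaction directionality.
    """
    cfg = cfg or ConsistencyConfig()
    relaxed = model.copy()
    for rx in relaxed.reactions.values():
        rx.lb = -cfg.big_M
        rx.ub = cfg.big_M
    res = check_fba(relaxed, cfg)
    res.mode = "bidirectional"
    return res


# ---------------------------------------------------------------------------
# Dynamic mode
# ---------------------------------------------------------------------------


def _dynamic_lp_parts(model: Model, cfg: ConsistencyConfig):
    S, row_index, rids, lb, ub = _prepared(model, cfg)
    if model.biomass is not None:
        j = rids.index(model.biomass)
        lb = lb.copy()
        lb[j] = max(lb[j], cfg.delta_growth)
        if lb[j] > ub[j]:
            # growth demand exceeds the biomass upper bound: infeasible by
            # construction, handled by the caller
            pass
    return S, row_index, rids, lb, ub


def check_dynamic(model: Model, cfg: Optional[ConsistencyConfig] = None) -> ConsistencyResult:
    """Producibility-under-growth check: one LP decides every species.

    Each non-boundary species s gets a dilution variable d_s ≥ 0 turning the
    steady state into S·v − d = 0, i.e. the network may overproduce and
    continuously drain any metabolite — the situation of a metabolite held
    at constant concentration during exponential growth.  When a biomass
    reaction is designated its flux is forced to at least δ (omitted
    otherwise, the draft-model case).  The LP maximizes Σ w_s with
    0 ≤ w_s ≤ min(ε, d_s); by superposition of dilution certificates the
    optimum drains every drainable species at once, so species s is blocked
    iff w_s ≤ ζ.  A reaction is blocked iff any of its reactants (species it
    consumes as written) is blocked.  If the LP is infeasible the model
    cannot grow at all: everything is reported blocked with a warning.
    """
    cfg = cfg or ConsistencyConfig()
    if not model.reactions:
        raise ValueError("model has no reactions")
    S, row_index, rids, lb, ub = _dynamic_lp_parts(model, cfg)
    m, n = S.shape
    sids = list(row_index)

    warnings: List[str] = []
    feasible = True
    w_opt = np.zeros(m)
    if model.biomass is not None and lb[rids.index(model.biomass)] > ub[rids.index(model.biomass)]:
        feasible = False
    else:
        # variables: v (n), d (m), w (m)
        A_eq = sparse.hstack(
            [S, -sparse.identity(m, format="csr"), sparse.csr_matrix((m, m))],
            format="csr",
        )
        b_eq = np.zeros(m)
        A_ub = sparse.hstack(
            [sparse.csr_matrix((m, n)), -sparse.identity(m, format="csr"),
             sparse.identity(m, format="csr")],
            format="csr",
        )
        b_ub = np.zeros(m)
        bounds = list(zip(lb, ub)) + [(0.0, None)] * m + [(0.0, cfg.eps)] * m
        c = np.zeros(n + 2 * m)
        c[n + m:] = -1.0
        res = _solve(c, A_ub, b_ub, A_eq, b_eq, bounds, "dynamic mode")
        if res is None:
            feasible = False
        else:
            w_opt = res.x[n + m:]

    if not feasible:
        warnings.append("growth LP infeasible: the model cannot sustain the "
                        "required biomass flux; everything reported blocked")
        sp_status = {sid: BLOCKED for sid in sids}
        rx_status = {rid: BLOCKED for rid in rids}
    else:
        sp_status = {
            sid: (ACTIVE if w_opt[i] > cfg.zero_tol else BLOCKED)
            for sid, i in row_index.items()
        }
        rx_status = {}
        for rid in rids:
            rx = model.reactions[rid]
            dead = any(
                sp_status.get(s) == BLOCKED for s, c0 in rx.stoich.items() if c0 < 0
            )
            rx_status[rid] = BLOCKED if dead else ACTIVE

    return ConsistencyResult(
        mode="dynamic",
        reaction_status=rx_status,
        species_status=sp_status,
        lp_count=1,
        config=cfg,
        warnings=warnings,
    )


def dynamic_species_oracle(model: Model, cfg: Optional[ConsistencyConfig] = None) -> Dict[str, str]:
    """Per-species dynamic-mode reference: one LP per species.

    Species s is active iff a flux vector exists with S·v − d = 0, d ≥ 0,
    the bounds and biomass flux ≥ δ (when designated) under which the
    dilution of s exceeds ζ.  Each LP maximizes that species' dilution
    (capped at ε, mirroring the single-LP weight variable) so the test is
    well above solver feasibility tolerance.  Used to validate the
    single-LP formulation.
    """
    cfg = cfg or ConsistencyConfig()
    S, row_index, rids, lb, ub = _dynamic_lp_parts(model, cfg)
    m, n = S.shape
    A_eq = sparse.hstack([S, -sparse.identity(m, format="csr")], format="csr")
    b_eq = np.zeros(m)
    out: Dict[str, str] = {}
    if model.biomass is not None and lb[rids.index(model.biomass)] > ub[rids.index(model.biomass)]:
        return {sid: BLOCKED for sid in row_index}
    for sid, i in row_index.items():
        d_bounds = [(0.0, None)] * m
        d_bounds[i] = (0.0, cfg.eps)
        bounds = list(zip(lb, ub)) + d_bounds
        c = np.zeros(n + m)
        c[n + i] = -1.0  # maximize d_s
        res = _solve(c, None, None, A_eq, b_eq, bounds, f"species {sid}")
        out[sid] = ACTIVE if (res is not None and -res.fun > cfg.zero_tol) else BLOCKED
    return out
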