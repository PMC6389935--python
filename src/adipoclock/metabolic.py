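"""Expression-constrained metabolic activity prediction (iMAT-style).

Time-point-wise pipeline: average gene expression is discretised into
inactive / neutral / active states (-1, 0, 1) by across-gene percentiles,
mapped onto reactions through gene-protein-reaction (GPR) boolean rules, and
a mixed-integer programme picks a steady-state flux distribution maximising
agreement with those states. Reactions whose predicted activity profile
changes state over the cycle and fits a 24-h cosinor with R^2 >= 0.8 are
called rhythmic.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, milp, Bounds

logger = logging.getLogger(__name__)

__all__ = [
    "Reaction",
    "MetabolicModel",
    "ReactionActivityProfile",
    "read_model_json",
    "write_model_json",
    "read_model_sbml",
    "discretize_expression",
    "parse_gpr",
    "eval_gpr",
    "map_gpr_states",
    "imat_solve",
    "activity_time_course",
    "rhythmic_reactions",
    "map_reactions_to_genes",
    "cosinor_r_squared",
]


class InfeasibleModelError(RuntimeError):
    """Raised when the stoichiometric constraints admit no flux."""


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]  # metabolite -> coefficient
    lb: float = 0.0
    ub: float = 1000.0
    gpr: str = ""
    subsystem: str = ""
    exchange: bool = False


@dataclass
class MetabolicModel:
    """Stoichiometric model: S matrix, bounds, GPR rules, gene list."""

    id: str
    metabolites: list[str]
    reactions: list[Reaction]
    genes: list[str]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoich.items():
                S[met_idx[met], j] = coef
        return S

    def validate(self) -> None:
        known = set(self.metabolites)
        gene_set = set(self.genes)
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        for rxn in self.reactions:
            if rxn.lb > rxn.ub:
                raise ValueError(f"{rxn.id}: lb > ub")
            unknown = set(rxn.stoich) - known
            if unknown:
                raise ValueError(f"{rxn.id}: unknown metabolites {unknown}")
            if rxn.gpr:
                for g in gpr_genes(rxn.gpr):
                    if g not in gene_set:
                        raise ValueError(f"{rxn.id}: GPR gene {g} not in model")


@dataclass
class ReactionActivityProfile:
    """Predicted -1/0/1 state of one reaction at each time point."""

    reaction_id: str
    states: np.ndarray
    has_state_change: bool
    cosinor_r_squared: float = np.nan
    is_rhythmic: bool = False


# ---------------------------------------------------------------------------
# model I/O

def write_model_json(model: MetabolicModel, path) -> None:
    payload = {
        "id": model.id,
        "metabolites": list(model.metabolites),
        "genes": list(model.genes),
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": r.lb,
                "ub": r.ub,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
                "exchange": r.exchange,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_model_json(path) -> MetabolicModel:
    with open(path) as fh:
        payload = json.load(fh)
    model = MetabolicModel(
        id=payload["id"],
        metabolites=list(payload["metabolites"]),
        genes=list(payload["genes"]),
        reactions=[
            Reaction(
                id=r["id"],
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                gpr=r.get("gpr", ""),
                subsystem=r.get("subsystem", ""),
                exchange=bool(r.get("exchange", False)),
            )
            for r in payload["reactions"]
        ],
    )
    model.validate()
    return model


def read_model_sbml(path) -> MetabolicModel:
    """Convert an SBML file to the native container (via cobrapy)."""
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    return MetabolicModel(
        id=cm.id or "sbml_model",
        metabolites=[m.id for m in cm.metabolites],
        genes=[g.id for g in cm.genes],
        reactions=[
            Reaction(
                id=r.id,
                stoich={m.id: c for m, c in r.metabolites.items()},
                lb=float(r.lower_bound),
                ub=float(r.upper_bound),
                gpr=r.gene_reaction_rule,
                subsystem=r.subsystem or "",
                exchange=r.boundary,
            )
            for r in cm.reactions
        ],
    )


# ---------------------------------------------------------------------------
# discretization

def discretize_expression(
    values: pd.Series | np.ndarray,
    low_pct: float = 20.0,
    high_pct: float = 80.0,
) -> pd.Series | np.ndarray:
    """Ternary gene states from across-gene percentiles at one time point.

    state -1 if value <= P[low_pct], 1 if value > P[high_pct], else 0.
    All-identical input yields all-neutral with a warning.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    arr = np.asarray(values, dtype=float)
    if np.ptp(arr) == 0:
        logger.warning("discretize_expression: all values identical; all neutral")
        states = np.zeros(arr.shape, dtype=int)
    else:
        lo = np.percentile(arr, low_pct)
        hi = np.percentile(arr, high_pct)
        states = np.where(arr <= lo, -1, np.where(arr > hi, 1, 0))
    if isinstance(values, pd.Series):
        return pd.Series(states, index=values.index)
    return states


# ---------------------------------------------------------------------------
# GPR rules

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(rule: str) -> list[str]:
    return _TOKEN.findall(rule)


def parse_gpr(rule: str):
    """Parse a GPR boolean rule into a nested ("and"|"or", [children]) tree.

    Leaves are gene identifier strings. Grammar (case-insensitive keywords):
    expr := term ("or" term)* ; term := factor ("and" factor)* ;
    factor := gene | "(" expr ")".
    """
    tokens = _tokenize(rule)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def expect_not_keyword(tok):
        if tok is None or tok in ("(", ")") or tok.lower() in ("and", "or"):
            raise ValueError(f"malformed GPR rule: {rule!r}")

    def parse_expr():
        nonlocal pos
        node = parse_term()
        parts = [node]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            parts.append(parse_term())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def parse_term():
        nonlocal pos
        node = parse_factor()
        parts = [node]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            parts.append(parse_factor())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def parse_factor():
        nonlocal pos
        tok = peek()
        if tok == "(":
            pos += 1
            node = parse_expr()
            if peek() != ")":
                raise ValueError(f"malformed GPR rule: {rule!r}")
            pos += 1
            return node
        expect_not_keyword(tok)
        pos += 1
        return tok

    tree = parse_expr()
    if pos != len(tokens):
        raise ValueError(f"malformed GPR rule: {rule!r}")
    return tree


def gpr_genes(rule: str) -> set[str]:
    """All gene identifiers referenced by a GPR rule."""
    genes: set[str] = set()

    def walk(node):
        if isinstance(node, str):
            genes.add(node)
        else:
            for child in node[1]:
                walk(child)

    walk(parse_gpr(rule))
    return genes


def eval_gpr(rule: str, gene_states: dict[str, int]) -> int:
    """Evaluate a GPR over ternary states: AND = min, OR = max.

    Genes absent from ``gene_states`` count as neutral (0).
    """

    def walk(node):
        if isinstance(node, str):
            return int(gene_states.get(node, 0))
        op, children = node
        vals = [walk(c) for c in children]
        return min(vals) if op == "and" else max(vals)

    return walk(parse_gpr(rule))


def map_gpr_states(
    model: MetabolicModel, gene_states: dict[str, int] | pd.Series
) -> pd.Series:
    """Per-reaction expression state; no GPR or malformed GPR -> neutral."""
    if isinstance(gene_states, pd.Series):
        gene_states = gene_states.to_dict()
    out = {}
    for rxn in model.reactions:
        if not rxn.gpr.strip():
            out[rxn.id] = 0
            continue
        try:
            out[rxn.id] = eval_gpr(rxn.gpr, gene_states)
        except ValueError:
            logger.warning("malformed GPR for %s; treated as neutral", rxn.id)
            out[rxn.id] = 0
    return pd.Series(out, name="state")


# ---------------------------------------------------------------------------
# iMAT MILP

def _effective_bounds(model: MetabolicModel, big: float) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([(-big if r.exchange else max(r.lb, -big)) for r in model.reactions])
    ub = np.array([(big if r.exchange else min(r.ub, big)) for r in model.reactions])
    return lb, ub


def imat_solve(
    model: MetabolicModel,
    reaction_states: pd.Series | dict[str, int],
    epsilon: float = 1.0,
    zero_tol: float = 1e-6,
    big: float = 1000.0,
) -> tuple[np.ndarray, pd.Series, int]:
    """Maximise congruency between reaction expression states and flux.

    Solves max (# state-1 reactions with |v| >= epsilon) + (# state-(-1)
    reactions with |v| <= zero_tol) subject to S v = 0 and bounds, with
    exchange reactions unbounded at +/- ``big``. A second lexicographic
    stage minimises sum |v| at optimal congruency so the reported flux (and
    hence the -1/0/1 activity states read off it) is canonical.

    Returns ``(flux, activity_states, congruency)``.
    """
    if isinstance(reaction_states, dict):
        reaction_states = pd.Series(reaction_states)
    if not epsilon > zero_tol >= 0:
        raise ValueError("require epsilon > zero_tol >= 0")
    nr = len(model.reactions)
    S = model.stoichiometric_matrix()
    lb, ub = _effective_bounds(model, big)
    states = np.array(
        [int(reaction_states.get(r.id, 0)) for r in model.reactions]
    )

    # variable layout: v (nr) then binaries
    cols: list[tuple[str, int]] = []  # (kind, reaction index)
    for j in np.flatnonzero(states == 1):
        if ub[j] >= epsilon:
            cols.append(("act+", j))
        if lb[j] <= -epsilon:
            cols.append(("act-", j))
    for j in np.flatnonzero(states == -1):
        cols.append(("off", j))
    nb = len(cols)
    nvar = nr + nb

    rows, cvals, conlb, conub = [], [], [], []

    def add_row(entries, lo, hi):
        rows.append(entries)
        conlb.append(lo)
        conub.append(hi)

    # steady state S v = 0
    for i in range(S.shape[0]):
        entries = [(j, S[i, j]) for j in range(nr) if S[i, j] != 0]
        add_row(entries, 0.0, 0.0)

    pair_seen: dict[int, int] = {}
    for b, (kind, j) in enumerate(cols):
        col = nr + b
        if kind == "act+":
            # v_j >= lb_j + y (epsilon - lb_j)
            add_row([(j, 1.0), (col, -(epsilon - lb[j]))], lb[j], np.inf)
            pair_seen.setdefault(j, 0)
            pair_seen[j] += 1
        elif kind == "act-":
            # v_j <= ub_j - y (ub_j + epsilon)
            add_row([(j, 1.0), (col, ub[j] + epsilon)], -np.inf, ub[j])
            pair_seen.setdefault(j, 0)
            pair_seen[j] += 1
        else:  # off
            # y=1 forces |v_j| <= zero_tol
            add_row([(j, 1.0), (col, ub[j] - zero_tol)], -np.inf, ub[j])
            add_row([(j, 1.0), (col, lb[j] + zero_tol)], lb[j], np.inf)
    # at most one direction counted per state-1 reaction
    for j, count in pair_seen.items():
        if count == 2:
            entries = [
                (nr + b, 1.0)
                for b, (kind, jj) in enumerate(cols)
                if jj == j and kind in ("act+", "act-")
            ]
            add_row(entries, -np.inf, 1.0)

    def build_constraint(extra_rows=(), extra_nvar=0):
        data, ri, ci = [], [], []
        all_rows = rows + list(extra_rows)
        for r_i, entries in enumerate(all_rows):
            for c, val in entries:
                ri.append(r_i)
                ci.append(c)
                data.append(val)
        A = sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(all_rows), nvar + extra_nvar)
        )
        return A

    integrality = np.zeros(nvar)
    integrality[nr:] = 1
    var_lb = np.concatenate([lb, np.zeros(nb)])
    var_ub = np.concatenate([ub, np.ones(nb)])

    c = np.zeros(nvar)
    c[nr:] = -1.0  # maximize number of satisfied binaries

    A = build_constraint()
    res = milp(
        c=c,
        constraints=LinearConstraint(A, np.array(conlb), np.array(conub)),
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
    )
    if res.status != 0 or res.x is None:
        raise InfeasibleModelError(
            f"iMAT stage 1 failed for model {model.id!r}: {res.message}"
        )
    congruency = int(round(-res.fun))

    # stage 2: fix congruency, minimise sum |v| (t_j >= |v_j|)
    extra_rows = []
    extra_lo, extra_hi = [], []
    for j in range(nr):
        extra_rows.append([(j, 1.0), (nvar + j, -1.0)])  # v - t <= 0
        extra_lo.append(-np.inf)
        extra_hi.append(0.0)
        extra_rows.append([(j, -1.0), (nvar + j, -1.0)])  # -v - t <= 0
        extra_lo.append(-np.inf)
        extra_hi.append(0.0)
    if nb:
        extra_rows.append([(nr + b, 1.0) for b in range(nb)])
        extra_lo.append(float(congruency))
        extra_hi.append(float(nb))

    A2 = build_constraint(extra_rows, extra_nvar=nr)
    c2 = np.zeros(nvar + nr)
    c2[nvar:] = 1.0
    res2 = milp(
        c=c2,
        constraints=LinearConstraint(
            A2,
            np.concatenate([conlb, extra_lo]),
            np.concatenate([conub, extra_hi]),
        ),
        integrality=np.concatenate([integrality, np.zeros(nr)]),
        bounds=Bounds(
            np.concatenate([var_lb, np.zeros(nr)]),
            np.concatenate([var_ub, np.full(nr, np.inf)]),
        ),
    )
    if res2.status != 0 or res2.x is None:
        logger.warning(
            "iMAT stage 2 non-optimal for %s; returning stage-1 flux", model.id
        )
        flux = res.x[:nr]
    else:
        flux = res2.x[:nr]

    activity = np.where(
        np.abs(flux) >= epsilon, 1, np.where(np.abs(flux) <= zero_tol, -1, 0)
    )
    return flux, pd.Series(activity, index=model.reaction_ids, name="activity"), congruency


# ---------------------------------------------------------------------------
# time-course assembly and rhythmicity

def activity_time_course(
    model: MetabolicModel,
    gene_expr: pd.DataFrame,
    low_pct: float = 20.0,
    high_pct: float = 80.0,
    epsilon: float = 1.0,
    zero_tol: float = 1e-6,
    big: float = 1000.0,
) -> list[ReactionActivityProfile]:
    """Run discretise -> GPR map -> iMAT independently per time point.

    ``gene_expr`` is gene x time point (participant-averaged log2 values).
    Returns one activity profile per reaction, flagged when the predicted
    state changes at least once over the cycle.
    """
    state_cols = []
    for col in gene_expr.columns:
        gene_states = discretize_expression(gene_expr[col], low_pct, high_pct)
        rxn_states = map_gpr_states(model, gene_states)
        _, activity, _ = imat_solve(model, rxn_states, epsilon, zero_tol, big)
        state_cols.append(activity.rename(col))
    states = pd.concat(state_cols, axis=1)
    profiles = []
    for rid in model.reaction_ids:
        s = states.loc[rid].to_numpy(dtype=int)
        profiles.append(
            ReactionActivityProfile(
                reaction_id=rid,
                states=s,
                has_state_change=bool(np.ptp(s) > 0),
            )
        )
    return profiles


def cosinor_r_squared(
    y: np.ndarray, times_h: np.ndarray, period_h: float = 24.0
) -> float:
    """R^2 of an ordinary least-squares 24-h cosinor (mesor + cos + sin)."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(times_h, dtype=float)
    w = 2 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return np.nan
    return float(1.0 - np.sum(resid**2) / sst)


def rhythmic_reactions(
    profiles: list[ReactionActivityProfile],
    times_h: np.ndarray,
    r2_threshold: float = 0.8,
    period_h: float = 24.0,
) -> list[ReactionActivityProfile]:
    """Keep state-changing profiles whose cosinor fit reaches the threshold.

    Constant profiles are excluded before fitting; the threshold is
    inclusive (R^2 >= 0.8 counts as rhythmic).
    """
    kept = []
    for prof in profiles:
        if not prof.has_state_change:
            continue
        r2 = cosinor_r_squared(prof.states.astype(float), times_h, period_h)
        prof.cosinor_r_squared = r2
        prof.is_rhythmic = bool(r2 >= r2_threshold)
        if prof.is_rhythmic:
            kept.append(prof)
    return kept


def map_reactions_to_genes(
    model: MetabolicModel, rhythmic: list[ReactionActivityProfile]
) -> dict[str, list[str]]:
    """Union of GPR genes of rhythmic reactions, grouped by subsystem."""
    rxn_by_id = {r.id: r for r in model.reactions}
    grouped: dict[str, set[str]] = {}
    for prof in rhythmic:
        rxn = rxn_by_id[prof.reaction_id]
        if not rxn.gpr.strip():
            continue
        grouped.setdefault(rxn.subsystem, set()).update(gpr_genes(rxn.gpr))
    return {k: sorted(v) for k, v in sorted(grouped.items())}


def write_reaction_states_tsv(
    profiles: list[ReactionActivityProfile], path
) -> None:
    n_t = len(profiles[0].states) if profiles else 0
    rows = []
    for p in profiles:
        row = {"reaction_id": p.reaction_id}
        row.update({f"state_t{i + 1}": int(s) for i, s in enumerate(p.states)})
        row["r_squared"] = p.cosinor_r_squared
        row["is_rhythmic"] = p.is_rhythmic
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
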