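"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

from adipoclock.metabolic import MetabolicModel


@pytest.fixture
def study_times_subjects():
    """A 7-subject x 5-biopsy DLMO-referenced design (deterministic)."""
    rng = np.random.default_rng(123)
    starts = rng.uniform(2.0, 5.0, size=7)
    times = (starts[:, None] + np.arange(5) * 6.0
             + rng.uniform(-0.5, 0.5, size=(7, 5)))
    subjects = np.repeat([f"S{i + 1:02d}" for i in range(7)], 5)
    return times.ravel(), subjects


def cosinor_values(times, mesor=5.0, amplitude=2.0, peak_h=8.8, slope=0.0,
                   period_h=24.0):
    return (mesor + slope * times
            + amplitude * np.cos(2 * np.pi * (times - peak_h) / period_h))


@pytest.fixture
def make_cosinor():
    return cosinor_values


def imat_brute_force(
    model: MetabolicModel,
    reaction_states: dict[str, int],
    epsilon: float = 1.0,
    zero_tol: float = 1e-6,
    big: float = 1000.0,
) -> int:
    """Maximum congruency by exhaustive enumeration of activation patterns.

    For every reaction with a nonzero expression state, enumerate how it
    could be satisfied (forward-active, reverse-active, or off) and test
    each combination for linear feasibility of S v = 0 within the adjusted
    bounds. Independent of the MILP route.
    """
    S = model.stoichiometric_matrix()
    lb = np.array([(-big if r.exchange else max(r.lb, -big))
                   for r in model.reactions])
    ub = np.array([(big if r.exchange else min(r.ub, big))
                   for r in model.reactions])
    idx = {r.id: j for j, r in enumerate(model.reactions)}

    options: list[list[tuple[int, tuple[float, float] | None, int]]] = []
    for rid, state in reaction_states.items():
        j = idx[rid]
        opts: list[tuple[int, tuple[float, float] | None, int]] = [(j, None, 0)]
        if state == 1:
            if ub[j] >= epsilon:
                opts.append((j, (epsilon, ub[j]), 1))
            if lb[j] <= -epsilon:
                opts.append((j, (lb[j], -epsilon), 1))
        elif state == -1:
            opts.append((j, (max(lb[j], -zero_tol), min(ub[j], zero_tol)), 1))
        options.append(opts)

    best = 0
    for combo in itertools.product(*options):
        score = sum(s for _, _, s in combo)
        if score <= best:
            continue
        blo, bhi = lb.copy(), ub.copy()
        ok = True
        for j, bnds, _ in combo:
            if bnds is None:
                continue
            blo[j] = max(blo[j], bnds[0])
            bhi[j] = min(bhi[j], bnds[1])
            if blo[j] > bhi[j]:
                ok = False
        if not ok:
            continue
        res = linprog(
            c=np.zeros(S.shape[1]),
            A_eq=S,
            b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(blo, bhi)),
            method="highs",
        )
        if res.status == 0:
            best = score
    return best


@pytest.fixture
def brute_force_imat():
    return imat_brute_force
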