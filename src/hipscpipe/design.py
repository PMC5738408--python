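"""Effective sample size (ESS) and study-design optimization for repeated-measures cohorts.

In hiPSC case/control studies each donor typically contributes several cell
lines, and expression measurements from the same donor are correlated.  The
fraction of expression variation attributable to donor (the "donor effect",
an intraclass correlation rho) determines how much statistical information a
replicate line adds.  Under a compound-symmetry correlation structure, a donor
with k replicates contributes k / (1 + (k-1)*rho) independent-sample
equivalents, so the design ESS is

    ESS = sum_i k_i / (1 + (k_i - 1) * rho)

(the reciprocal of the Kish design effect summed over donors).  A new donor
always adds exactly one unit of ESS; a replicate from an existing donor adds
less than one unit whenever rho > 0.

``optimize_design`` searches the feasible designs under a budget where a donor
(including their first line) costs ``c_d`` and each additional line costs
``alpha * c_d``, and returns the ESS-maximizing allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ESSReport", "DesignSpec", "ess", "ess_increment", "optimize_design"]


@dataclass
class ESSReport:
    """ESS of a repeated-measures design.

    Attributes
    ----------
    n_samples : total number of samples (sum of replicate counts).
    n_donors : number of donors.
    ess : effective sample size, in [n_donors, n_samples].
    per_donor : ESS contribution of each donor.
    marginal_new_donor : ESS gained by adding a donor with one line (always 1).
    marginal_new_replicate : ESS gained by one more line from the donor with
        the fewest lines (the best place to add a replicate).
    rho : donor effect used.
    """

    n_samples: int
    n_donors: int
    ess: float
    per_donor: list[float]
    marginal_new_donor: float
    marginal_new_replicate: float
    rho: float


@dataclass
class DesignSpec:
    """A repeated-measures design: replicate counts per donor plus cost model."""

    k_list: list[int]
    rho: float
    cost_per_donor: float = 1.0
    alpha: float = 1.0  # relative cost of an additional line, in (0, 1]
    budget: float | None = None

    @property
    def cost(self) -> float:
        k = np.asarray(self.k_list)
        return float(np.sum(self.cost_per_donor * (1.0 + self.alpha * (k - 1))))


def _check_rho(rho: float) -> float:
    rho = float(rho)
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"donor effect rho must be in [0, 1], got {rho}")
    return rho


def ess(k_list: Sequence[int], rho: float) -> ESSReport:
    """Effective sample size of a design with ``k_list[i]`` replicates per donor."""
    rho = _check_rho(rho)
    k = np.asarray(list(k_list), dtype=float)
    if k.size == 0:
        raise ValueError("k_list is empty")
    if np.any(k < 1) or np.any(k != np.round(k)):
        raise ValueError("replicate counts must be integers >= 1")
    per_donor = k / (1.0 + (k - 1.0) * rho)
    k_min = int(k.min())
    return ESSReport(
        n_samples=int(k.sum()),
        n_donors=int(k.size),
        ess=float(per_donor.sum()),
        per_donor=per_donor.tolist(),
        marginal_new_donor=1.0,
        marginal_new_replicate=ess_increment(k_min, rho),
        rho=rho,
    )


def ess_increment(current_k: int, rho: float) -> float:
    """Marginal ESS of adding one line to a donor who already has ``current_k``.

    ``current_k = 0`` means recruiting a new donor, which adds exactly 1 for
    every value of the donor effect.
    """
    rho = _check_rho(rho)
    k = int(current_k)
    if k < 0:
        raise ValueError("current_k must be >= 0")
    if k == 0:
        return 1.0
    before = k / (1.0 + (k - 1.0) * rho)
    after = (k + 1.0) / (1.0 + k * rho)
    return float(after - before)


def optimize_design(
    budget: float,
    cost_per_donor: float,
    alpha: float,
    rho: float,
    constraint: str = "budget",
    n_donors: int | None = None,
    max_k: int = 10,
) -> tuple[DesignSpec, ESSReport]:
    """Find the ESS-maximizing feasible design.

    Searches over the number of donors m and the number of extra lines L,
    spreading the L extra lines as evenly as possible over the m donors.
    This covers the optimum because, at fixed m and L, the near-even spread
    maximizes the ESS (the per-donor ESS contribution is concave in the
    replicate count), so only (m, L) need enumerating.

    Parameters
    ----------
    budget : total budget B (same units as cost_per_donor).
    cost_per_donor : cost of recruiting a donor including their first line.
    alpha : relative cost of each additional line, in (0, 1].
    rho : donor effect.
    constraint : "budget" (spend at most B, any number of donors) or
        "n_donors" (exactly ``n_donors`` donors, spend at most B on lines).
    n_donors : required when constraint="n_donors".
    max_k : largest replicate count considered per donor.

    Ties are broken toward fewer total lines, then toward more donors (a
    design spread over more independent donors is preferred at equal ESS and
    equal size).
    """
    rho = _check_rho(rho)
    if cost_per_donor <= 0:
        raise ValueError("cost_per_donor must be positive")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if budget < cost_per_donor:
        raise ValueError("budget below the cost of a single donor: no feasible design")

    def spread(m: int, extra: int) -> list[int]:
        """m donors with ``extra`` additional lines spread as evenly as possible."""
        base, rem = divmod(extra, m)
        return [1 + base + 1] * rem + [1 + base] * (m - rem)

    candidates: list[tuple[float, int, int, list[int]]] = []

    if constraint == "budget":
        m_max = int(budget // cost_per_donor)
        for m in range(1, m_max + 1):
            left = budget - m * cost_per_donor
            extra_max = min(int((left + 1e-9) // (alpha * cost_per_donor)),
                            m * (max_k - 1))
            for extra in range(extra_max + 1):
                k_list = spread(m, extra)
                rep = ess(k_list, rho)
                candidates.append((rep.ess, -rep.n_samples, len(k_list), k_list))
    elif constraint == "n_donors":
        if n_donors is None or n_donors < 1:
            raise ValueError("constraint='n_donors' requires n_donors >= 1")
        if n_donors * cost_per_donor > budget:
            raise ValueError("budget cannot cover the requested number of donors")
        left = budget - n_donors * cost_per_donor
        extra_max = min(int((left + 1e-9) // (alpha * cost_per_donor)),
                        n_donors * (max_k - 1))
        for extra in range(extra_max + 1):
            k_list = spread(n_donors, extra)
            rep = ess(k_list, rho)
            candidates.append((rep.ess, -rep.n_samples, len(k_list), k_list))
    else:
        raise ValueError(f"unknown constraint {constraint!r}")

    if not candidates:
        raise ValueError("no feasible design found")
    best = max(candidates, key=lambda c: (c[0], c[1], c[2]))
    k_list = best[3]
    spec = DesignSpec(k_list=k_list, rho=rho, cost_per_donor=cost_per_donor,
                      alpha=alpha, budget=budget)
    return spec, ess(k_list, rho)
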