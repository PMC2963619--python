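"""Flux-spectrum and alpha-spectrum analyses built on the FVA sweep.

The *flux-spectrum* is variability analysis without the optimality
requirement: the objective cut is taken at gamma = 0, optionally after
fixing selected fluxes to measured values.  The *alpha-spectrum* asks the
same min/max question about the nonnegative weights alpha of extreme
pathways: with P holding the extreme pathways as its columns, any
steady-state flux distribution decomposes as v = P alpha with alpha >= 0,
and the spectrum is the attainable range of each weight.

Two alpha-spectrum readings are exposed:

* ``target="literal"`` substitutes P for S verbatim, i.e. solves over
  {alpha >= 0 : P alpha = 0}.  Because extreme-pathway columns and weights
  are nonnegative wherever the flux cone is pointed, this region often
  collapses to alpha = 0; the mode is kept for fidelity.
* the default *reconstruction* mode constrains P alpha = v_target for a
  supplied flux vector (entries may be NaN to leave a reaction's row
  unconstrained), which is the published alpha-spectrum formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .fva_engine import FVAConfig, FVAResult, InfeasibleRegionError, _sweep, run_fva
from .lp_core import LPProblem, get_backend
from .model_io import MetabolicModel

__all__ = ["PathwayMatrix", "flux_spectrum", "alpha_spectrum",
           "read_pathway_tsv", "write_pathway_tsv", "read_pathway_mtx"]


@dataclass
class PathwayMatrix:
    """Extreme pathways as columns: P is n_reactions x p."""

    P: np.ndarray
    pathway_ids: list[str]
    reaction_ids: list[str]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        n, p = self.P.shape
        if len(self.pathway_ids) != p:
            raise ValueError("pathway_ids length != number of P columns")
        if len(self.reaction_ids) != n:
            raise ValueError("reaction_ids length != number of P rows")
        if not np.all(np.isfinite(self.P)):
            raise ValueError("P contains non-finite entries")


def flux_spectrum(model: MetabolicModel, config: Optional[FVAConfig] = None,
                  measured: Optional[dict[str, float]] = None) -> FVAResult:
    """Flux ranges with no optimality requirement (gamma = 0).

    ``measured`` maps reaction IDs to experimentally fixed flux values;
    each is imposed by clamping that reaction's bounds to the value, which
    must lie inside the original bounds.
    """
    config = config or FVAConfig()
    cfg = FVAConfig(gamma=0.0, reaction_subset=config.reaction_subset,
                    backend=config.backend, order=config.order,
                    chunks=config.chunks,
                    include_objective_cut=config.include_objective_cut,
                    collect_vectors=config.collect_vectors,
                    options=config.options)
    if measured:
        lo = model.lower_bounds.copy()
        up = model.upper_bounds.copy()
        for rid, value in measured.items():
            j = model.reaction_index(rid)
            if not (lo[j] - 1e-9 <= value <= up[j] + 1e-9):
                raise ValueError(
                    f"measured flux {value} for reaction {rid!r} outside its "
                    f"bounds [{lo[j]}, {up[j]}]")
            lo[j] = up[j] = value
        model = MetabolicModel(model.model_id, list(model.metabolite_ids),
                               list(model.reaction_ids), model.S, lo, up,
                               model.objective, model.objective_sense)
    return run_fva(model, cfg)


def alpha_spectrum(pathways: PathwayMatrix,
                   target: Union[str, np.ndarray, Sequence[float]] = "literal",
                   alpha_upper: Optional[np.ndarray] = None,
                   config: Optional[FVAConfig] = None) -> FVAResult:
    """Min/max extreme-pathway weights via the warm-start sweep (1 + 2p LPs).

    ``target="literal"`` solves over P·alpha = 0; otherwise ``target`` is a
    flux vector v_target of length n_reactions and the system is
    P·alpha = v_target, with NaN entries leaving the corresponding row
    unconstrained.  alpha >= 0 always; ``alpha_upper`` defaults to +inf.
    """
    config = config or FVAConfig(gamma=0.0)
    P = pathways.P
    n, p = P.shape
    if isinstance(target, str):
        if target != "literal":
            raise ValueError("target must be 'literal' or a flux vector")
        rhs_lo = np.zeros(n)
        rhs_up = np.zeros(n)
    else:
        v_target = np.asarray(target, dtype=float)
        if v_target.shape != (n,):
            raise ValueError(
                f"v_target length {v_target.size} != number of reactions {n}")
        free = np.isnan(v_target)
        rhs_lo = np.where(free, -np.inf, v_target)
        rhs_up = np.where(free, np.inf, v_target)
    alpha_up = (np.full(p, np.inf) if alpha_upper is None
                else np.asarray(alpha_upper, dtype=float))
    if alpha_up.shape != (p,):
        raise ValueError("alpha_upper length != number of pathways")

    problem = LPProblem(sp.csc_matrix(P), rhs_lo, rhs_up, np.zeros(p),
                        alpha_up, np.zeros(p), "maximize")

    # initial feasibility solve (zero objective) provides the warm basis
    be = get_backend(config.backend)
    if hasattr(be, "options") and config.options is not None:
        be.options = config.options
    be.load(problem, presolve=True)
    init = be.solve()
    if init.status == "infeasible":
        raise InfeasibleRegionError(
            "no nonnegative pathway-weight vector satisfies the target system")

    mins, maxs, st_min, st_max, vmin, vmax, state = _sweep(
        problem, list(range(p)), config.backend, init.basis, config.order,
        config.chunks, True, 0.0, 0.0, config.options, config.collect_vectors)

    return FVAResult(
        model_id="alpha_spectrum",
        reaction_ids=list(pathways.pathway_ids),
        Z0=float(init.objective_value) if init.status == "optimal" else np.nan,
        gamma=0.0,
        min_flux=mins,
        max_flux=maxs,
        status_min=st_min,
        status_max=st_max,
        lp_solve_count=1 + state["solves"],
        total_pivots=init.pivot_count + state["pivots"],
        warm=True,
        min_vectors=vmin,
        max_vectors=vmax,
    )


# ---------------------------------------------------------------------
# pathway matrix I/O
# ---------------------------------------------------------------------

def read_pathway_tsv(path: str) -> PathwayMatrix:
    """TSV with header = pathway IDs and first column = reaction IDs."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return PathwayMatrix(df.to_numpy(dtype=float),
                         [str(c) for c in df.columns],
                         [str(i) for i in df.index])


def write_pathway_tsv(pathways: PathwayMatrix, path: str) -> None:
    import pandas as pd

    pd.DataFrame(pathways.P, index=pathways.reaction_ids,
                 columns=pathways.pathway_ids).to_csv(path, sep="\t")


def read_pathway_mtx(mtx_path: str, reaction_ids_path: str,
                     pathway_ids_path: str) -> PathwayMatrix:
    """Matrix-market P plus two plain-text ID files (one ID per line)."""
    from scipy.io import mmread

    from .model_io import read_reaction_subset

    M = mmread(mtx_path)
    P = np.asarray(M.todense() if sp.issparse(M) else M, dtype=float)
    return PathwayMatrix(P, read_reaction_subset(pathway_ids_path),
                         read_reaction_subset(reaction_ids_path))
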