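"""End-to-end analysis pipeline and report export.

:func:`run_paper_pipeline` chains the full analysis on one measurement set:
model-vs-observed digest tables for the three parametric families, the
feasibility scan over chain lengths (with and without homogeneity), the
maximum-entropy composition/bound/transition profiles, and the
mixture-of-lengths analyses. Results are returned as one JSON-serializable
dictionary and optionally written as ``report.json`` plus CSV tables; every
stochastic stage records its seed and each report carries provenance
(input hash, configuration, solver versions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .constraint_system import assemble, rank
from .digest_model import hc_distribution, hi_distribution, ni_distribution
from .length_mixture import gaussian_length_distribution, per_length_composition
from .measurements import MeasurementSet, to_dict
from .parametric_fitting import SAConfig, digest_objective, fit_hc, fit_ni
from .polytope_analysis import (
    bounds_profile,
    feasibility_scan,
    marginal_profile,
    solve_maxent,
    transition_profile,
)
from .species_space import build_space

__all__ = ["RunConfig", "run_paper_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; the seed is recorded in every output artifact."""

    seed: int = 0
    n: int | None = None              # chain length (default: ms.mean_length)
    scan_range: tuple[int, int] = (10, 16)
    restarts: int = 100
    sa: SAConfig | None = None
    mixture_lengths: tuple[int, int] | None = None
    mixture_sigma: float | None = None
    feasible_tol: float = 1e-8
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.feasible_tol <= 0:
            raise ValueError("tolerances must be positive")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_paper_pipeline(ms: MeasurementSet, config: RunConfig | None = None) -> dict:
    """Run every analysis stage on ``ms``; return the report bundle."""
    config = config or RunConfig()
    n = config.n or ms.mean_length
    sa = config.sa or SAConfig(restarts=config.restarts, seed=config.seed)
    fixture_hash = hashlib.sha256(
        json.dumps(to_dict(ms), sort_keys=True).encode()
    ).hexdigest()
    report: dict = {
        "provenance": {
            "package": f"glycopoly {__version__}",
            "scipy": scipy.__version__,
            "numpy": np.__version__,
            "seed": config.seed,
            "fixture_sha256": fixture_hash,
            "config": _jsonable({**asdict(config), "sa": asdict(sa)}),
        }
    }

    # -- parametric digest models: observed vs predicted per enzyme --------
    hc = fit_hc(ms, n, sa)
    ni = fit_ni(ms, n, sa)
    models = {}
    for d in ms.digests:
        models[d.enzyme] = {
            "observed": d.probs,
            "hi": hi_distribution(ms.table, n, d.enzyme, d.cap).g,
            "hc": hc_distribution(hc.params.P, ms.table, n, d.enzyme, d.cap).g,
            "ni": ni_distribution(ni.params.Gamma, ms.table, n, d.enzyme, d.cap).g,
        }
    report["digest_models"] = {
        "per_enzyme": models,
        "objectives": {
            "hi": digest_objective("hi", ms, n),
            "hc": hc.objective,
            "ni": ni.objective,
        },
        "hc_P": hc.params.P,
        "ni_gamma_S": ni.params.Gamma[:, 0],
        "sa_seed": sa.seed,
    }

    # -- feasibility scans --------------------------------------------------
    scan = feasibility_scan(ms, config.scan_range)
    scan_h = feasibility_scan(
        ms, config.scan_range, parts=("norm", "homogeneity", "digests")
    )
    feasible_ns = scan.loc[scan["feasible"], "n"]
    report["feasibility"] = {
        "composition_plus_digests": scan.to_dict(orient="list"),
        "homogeneity_plus_digests": scan_h.to_dict(orient="list"),
        "smallest_feasible_n": int(feasible_ns.min()) if len(feasible_ns) else None,
    }

    # -- polytope at the working length ------------------------------------
    space = build_space([n])
    cs = assemble(ms, space)
    sol = solve_maxent(cs)
    bounds = bounds_profile(cs, space)
    report["polytope"] = {
        "n": n,
        "n_rows": cs.shape[0],
        "rank": rank(cs),
        "maxent_entropy": sol.entropy,
        "maxent_residual": sol.residual,
        "marginal_profile": marginal_profile(sol.p, space).to_dict(orient="list"),
        "transition_profile": transition_profile(sol.p, space).to_dict(orient="list"),
        "bounds": {
            "position": bounds.positions,
            "lower": bounds.lower,
            "upper": bounds.upper,
        },
    }

    # -- mixture of chain lengths (optional) --------------------------------
    if config.mixture_lengths is not None:
        lo, hi = config.mixture_lengths
        sigma = config.mixture_sigma if config.mixture_sigma is not None else (
            ms.sigma or 3.5)
        w = gaussian_length_distribution(ms.mean_length, sigma, lo, hi)
        mspace = build_space(w.lengths)
        mcs = assemble(ms, mspace, w=w.w)
        msol = solve_maxent(mcs)
        report["mixture"] = {
            "lengths": list(w.lengths),
            "w": w.w,
            "sigma": sigma,
            "maxent_residual": msol.residual,
            "composition_by_length":
                per_length_composition(msol.p, mspace).to_dict(orient="list"),
            "bounds_re": {
                "position": (b := bounds_profile(
                    mcs, mspace, alignment="re",
                    positions=range(1, min(w.lengths) + 1))).positions,
                "lower": b.lower,
                "upper": b.upper,
            },
        }

    report = _jsonable(report)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        pd.DataFrame(report["feasibility"]["composition_plus_digests"]).to_csv(
            out / "feasibility_scan.csv", index=False)
        pd.DataFrame(report["polytope"]["marginal_profile"]).to_csv(
            out / "maxent_profile.csv", index=False)
        pd.DataFrame(report["polytope"]["bounds"]).to_csv(
            out / "bounds_profile.csv", index=False)
    return report
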