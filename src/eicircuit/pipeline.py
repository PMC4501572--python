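"""End-to-end orchestration: dictionary → G → factorization → simulation →
analyses, with all artifacts persisted under one output directory.

A run is fully described by a :class:`RunConfig` (serializable to/from
YAML) plus its root seed; named random substreams are derived from the
root seed for the dictionary, the stimuli, and the solver so that every
stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .analysis import (ei_ratio, population_tuning_summary,
                       weight_distribution)
from .archive import load_arrays, save_arrays
from .arpca import ARPCAConfig, adaptive_rpca
from .decompositions import (direct_factorization, gramian_factorization,
                             rpca_factorization, svd_factorization,
                             variance_explained)
from .dictionary import gram_matrix, load_dictionary
from .ei_network import equivalence_report
from .errors import ParameterError
from .fixtures import make_standard_fixture
from .lca import LCAParams
from .stimuli import default_grating_set

logger = logging.getLogger(__name__)


def _substream_seed(root_seed: int, name: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the root."""
    ss = np.random.SeedSequence([root_seed,
                                 zlib.crc32(name.encode()) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    scale: str = "small"               # standard fixture scale, or "load"
    dictionary_path: str | None = None  # used when scale == "load"
    scheme: str = "rpca"               # direct | gramian | svd | rpca
    rank_r: int | None = None          # None → smallest rank w/ var. target
    variance_target: float = 0.99
    seed: int = 0
    lca: dict = field(default_factory=dict)      # LCAParams overrides
    arpca: dict = field(default_factory=dict)    # ARPCAConfig overrides
    dynamic_steps: int = 100
    run_dynamic: bool = True
    run_tuning: bool = False
    run_weights: bool = True
    max_cells_per_population: int | None = 25
    output_dir: str = "eicircuit_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _pick_rank(matrix: np.ndarray, target: float) -> int:
    """Smallest rank whose eigenvalue mass reaches ``target``."""
    import scipy.linalg
    vals = np.clip(scipy.linalg.eigvalsh(0.5 * (matrix + matrix.T)),
                   0.0, None)[::-1]
    cum = np.cumsum(vals) / vals.sum()
    return int(np.searchsorted(cum, target) + 1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write archives, CSVs and a JSON
    summary under ``cfg.output_dir``; returns the summary dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(cfg)}
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    try:
        name = stage("dictionary")
        if cfg.scale == "load":
            if not cfg.dictionary_path:
                raise ParameterError("scale='load' needs dictionary_path")
            d = load_dictionary(cfg.dictionary_path)
            g = gram_matrix(d)
        else:
            d, g = make_standard_fixture(
                cfg.scale, seed=_substream_seed(cfg.seed, "dictionary"))
        summary["n_pixels"] = d.n_pixels
        summary["n_elements"] = d.n_elements
        done(name)

        name = stage("decompose")
        arpca_res = None
        if cfg.scheme == "direct":
            f = direct_factorization(g)
        elif cfg.scheme == "gramian":
            f = gramian_factorization(d)
        elif cfg.scheme in ("svd", "rpca"):
            if cfg.scheme == "rpca":
                acfg = ARPCAConfig(seed=_substream_seed(cfg.seed, "solver"),
                                   **cfg.arpca)
                arpca_res = adaptive_rpca(g, acfg)
                arpca_res.diagnostics.to_csv(out / "arpca_diagnostics.csv",
                                             index=False)
                basis = arpca_res.l
            else:
                basis = g.g
            rank = cfg.rank_r or _pick_rank(basis, cfg.variance_target)
            summary["rank_r"] = rank
            summary["variance_explained"] = variance_explained(basis, rank)
            f = rpca_factorization(arpca_res, rank) if cfg.scheme == "rpca" \
                else svd_factorization(g, rank)
        else:
            raise ParameterError(f"unknown scheme {cfg.scheme!r}")
        summary["counts"] = f.counts
        summary["ei_ratio"] = ei_ratio(f, d.n_elements)
        save_arrays(out / "factorization.h5",
                    {f"in_{n}": w for n, w in zip(f.population_names,
                                                  f.inhib_in)}
                    | {f"out_{n}": w for n, w in zip(f.population_names,
                                                     f.inhib_out)}
                    | {"g_excite_direct": f.g_excite_direct},
                    meta={"scheme": f.scheme,
                          "total_interneurons": f.counts["total"]})
        done(name)

        name = stage("simulate")
        p = LCAParams(**cfg.lca)
        stimuli = default_grating_set(d.patch_edge)
        rep_inst = equivalence_report(d, stimuli, f, p, "instantaneous")
        rep_inst.per_stimulus.to_csv(out / "equivalence_instantaneous.csv",
                                     index=False)
        summary["instantaneous"] = rep_inst.summary()
        if cfg.run_dynamic:
            p_dyn = LCAParams(**{**cfg.lca, "n_steps": cfg.dynamic_steps})
            rep_dyn = equivalence_report(d, stimuli, f, p_dyn, "dynamic")
            rep_dyn.per_stimulus.to_csv(out / "equivalence_dynamic.csv",
                                        index=False)
            summary["dynamic"] = rep_dyn.summary()
        done(name)

        name = stage("analyze")
        if cfg.run_weights and f.counts["total"] > 0:
            wd = weight_distribution(f)
            summary["weight_lower_tail_excess"] = wd.lower_tail_excess
            np.savetxt(out / "weight_qq.csv", wd.qq_points,
                       delimiter=",", header="theoretical,empirical",
                       comments="")
        if cfg.run_tuning and f.scheme == "rpca":
            tuning = population_tuning_summary(
                d, f, p,
                max_cells_per_population=cfg.max_cells_per_population,
                seed=_substream_seed(cfg.seed, "tuning"))
            summary["tuning"] = {
                k: {kk: vv for kk, vv in v.items() if kk != "osi"}
                if isinstance(v, dict) else v
                for k, v in tuning.items()}
        done(name)
    except Exception:
        summary["timings_s"] = {k: round(v, 3) for k, v in timings.items()
                                if not isinstance(v, float) or v < 1e9}
        save_report(summary, out / "summary_partial.json")
        raise

    summary["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    save_report(summary, out / "summary.json")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def save_report(summary: dict, path: str | Path) -> None:
    """Write a run summary as JSON (numpy types converted)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)


def load_archive(path: str | Path) -> tuple[dict, dict]:
    """Load a named-matrix archive written by any stage."""
    return load_arrays(path)
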