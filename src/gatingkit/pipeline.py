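"""End-to-end runs: simulate every construct, analyze, pair up ddG values.

``run_end_to_end`` is deterministic for a fixed config seed: every stream of
randomness (test sweeps and P/N companions of each construct) draws from a
seed derived from the config seed and the construct's position.  Output CSVs
carry a provenance header (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .charge import fit_double_boltzmann, normalize_qv, qv_from_sweeps
from .config import (
    DEFAULT_GATING_PROTOCOL,
    RunConfig,
    build_protocol,
    build_scheme,
)
from .constants import PhysicalConstants
from .ionic import delta_delta_g, fit_boltzmann, gv_from_chord, gv_from_tails, p_over_n_subtract
from .simulate import CellModel, simulate_p_over_n, simulate_sweeps

log = logging.getLogger("gatingkit")


class StageError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _derived_seed(base: int, index: int) -> int:
    return (base * 1000003 + 7919 * (index + 1)) % 2**31


def _write_csv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(provenance)
        df.to_csv(fh, index=False)


def run_end_to_end(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyze every configured construct; return a summary dict.

    Ionic constructs go through P/8 subtraction, G-V extraction (tail or
    chord per the analysis options) and a Boltzmann fit; gating constructs go
    through the OFF-charge Q-V pipeline and a double-Boltzmann fit; configured
    (aa, ah) pairs yield ddG values.  CSV outputs and a machine-readable
    summary are written to ``outdir`` when given.
    """
    constants = PhysicalConstants(temperature_K=config.analysis.temperature_K)
    chash = _config_hash(config)
    provenance = f"# gatingkit {__version__} config_hash={chash} seed={config.seed}\n"
    summary: dict = {
        "version": __version__, "config_hash": chash, "seed": config.seed,
        "constructs": {}, "ddg": {}, "flags": [],
    }
    gv_rows, qv_rows, ddg_rows = [], [], []
    fits = {}
    for idx, (name, cspec) in enumerate(config.constructs.items()):
        t_start = time.perf_counter()
        seed = _derived_seed(config.seed, idx)
        scheme = build_scheme(cspec.scheme, constants)
        cell = CellModel(seed=seed, **config.cell.model_dump())
        if cspec.mode == "ionic":
            proto = build_protocol(config.protocol)
            try:
                test = simulate_sweeps(scheme, proto, cell)
                subs = simulate_p_over_n(scheme, proto, cell, n=config.p_over_n)
                corrected = p_over_n_subtract(test, subs, n=config.p_over_n)
            except Exception as exc:
                raise StageError(f"[simulate] construct {name!r}: {exc}") from exc
            try:
                if config.analysis.method == "chord":
                    curve = gv_from_chord(corrected, Vrev=config.analysis.Vrev)
                else:
                    curve = gv_from_tails(corrected, window=config.analysis.tail_window)
                fit = fit_boltzmann(curve, constants, with_offset=(curve.method == "tail"), label=name)
            except Exception as exc:
                raise StageError(f"[gv] construct {name!r}: {exc}") from exc
            fits[name] = fit
            if not fit.converged:
                summary["flags"].append(f"gv_fit_not_converged:{name}")
            gv_rows.append({
                "construct": name, "method": curve.method, "Vd_mV": fit.Vd, "z_e0": fit.z,
                "Gmax": fit.Gmax, "sd_Vd": fit.sd_Vd, "sd_z": fit.sd_z,
                "converged": fit.converged, "n_points": curve.voltages.size,
            })
            summary["constructs"][name] = {
                "mode": "ionic", "Vd_mV": fit.Vd, "z_e0": fit.z, "converged": fit.converged,
            }
        else:  # gating
            gspec = config.gating_protocol or DEFAULT_GATING_PROTOCOL
            proto = build_protocol(gspec)
            gating_scheme = replace(scheme, conducting=False)
            try:
                sweeps = simulate_sweeps(gating_scheme, proto, cell)
                qv = qv_from_sweeps(sweeps, fit_range=config.analysis.cap_fit_range)
                qfit = fit_double_boltzmann(qv, constants)
                if qfit.converged and qfit.Qmax > 0:
                    normalize_qv(qv, qfit)
            except Exception as exc:
                raise StageError(f"[qv] construct {name!r}: {exc}") from exc
            if not qfit.converged:
                summary["flags"].append(f"qv_fit_not_converged:{name}")
            summary["flags"].extend(f"qv:{name}:{f}" for f in qfit.flags)
            qv_rows.append({
                "construct": name, "Qmax_nC": qfit.Qmax, "f1": qfit.f1,
                "V1_mV": qfit.V1, "z1_e0": qfit.z1, "V2_mV": qfit.V2, "z2_e0": qfit.z2,
                "C_lin_nC_per_mV": qv.c_lin, "converged": qfit.converged,
                "flags": ";".join(qfit.flags),
            })
            summary["constructs"][name] = {
                "mode": "gating", "f1": qfit.f1, "V1_mV": qfit.V1, "z1_e0": qfit.z1,
                "V2_mV": qfit.V2, "z2_e0": qfit.z2, "C_lin_nC_per_mV": qv.c_lin,
                "converged": qfit.converged,
            }
        log.info("construct %s analyzed in %.2f s", name, time.perf_counter() - t_start)
    for aa, ah in config.pairs:
        if aa not in fits or ah not in fits:
            raise StageError(f"[ddg] pair ({aa}, {ah}) requires two ionic constructs")
        try:
            ddg = delta_delta_g(fits[aa], fits[ah], constants)
        except Exception as exc:
            raise StageError(f"[ddg] pair ({aa}, {ah}): {exc}") from exc
        key = f"{aa}/{ah}"
        ddg_rows.append({
            "pair": key, "ddG_kcal_mol": ddg.value,
            "term_aa_kcal_mol": ddg.term_aa, "term_ah_kcal_mol": ddg.term_ah, "sd": ddg.sd,
        })
        summary["ddg"][key] = ddg.value
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = config.output_prefix
        if gv_rows:
            _write_csv(pd.DataFrame(gv_rows), outdir / f"{prefix}_gv_fits.csv", provenance)
        if qv_rows:
            _write_csv(pd.DataFrame(qv_rows), outdir / f"{prefix}_qv_fits.csv", provenance)
        if ddg_rows:
            _write_csv(pd.DataFrame(ddg_rows), outdir / f"{prefix}_ddg.csv", provenance)
        (outdir / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
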