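"""End-to-end orchestration: PVT -> fit -> mixing rules -> sorption -> reports.

A :class:`RunConfig` (YAML on disk, or a plain dict) names the polymers,
gases, interaction coefficients and condition grids; :func:`run_pipeline`
executes the stages in order and writes provenance-stamped CSV tables, a
JSON summary and a structured log into the output directory.  Re-running
with the same configuration and seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .copolymer import parameter_trend
from .errors import DomainError, PipelineStageError, SlsorbError
from .eos import SLParams
from .fugacity import PRComponent
from .io import read_pvt, write_json, write_pvt, write_table
from .pvtfit import fit_sl_params
from .reference import (
    GAS_POLYMER_KIJ,
    GAS_PR,
    GAS_SL,
    K_PR_CO2_CH4,
    KIJ_GAS_GAS,
    PHBV_PARAMS,
    T_SORPTION,
)
from .sorption import (
    SorptionSystem,
    mixed_vs_ideal_selectivity,
    pure_gas_isotherm,
    sensitivity_sweep,
)
from .synthetic import PVTGridSpec, generate_pvt

__all__ = ["RunConfig", "run_pipeline", "default_config"]

logger = logging.getLogger("slsorb.pipeline")


def default_config():
    """Configuration dict reproducing the package's reference workflow.

    Synthetic PVT is generated and re-fitted for the endpoint polymers,
    copolymer parameters are tabulated across the composition range, and
    the pure-/mixed-gas sorption, selectivity and sensitivity studies are
    run at 35 degC up to 30 bar.
    """
    return {
        "seed": 0,
        "outdir": "slsorb-run",
        "temperature": T_SORPTION,
        "polymers": [
            {
                "label": params.label,
                "hv_mol_percent": hv,
                "params": {
                    "Tstar": params.Tstar,
                    "pstar": params.pstar,
                    "rhostar": params.rhostar,
                },
            }
            for hv, params in sorted(PHBV_PARAMS.items())
        ],
        "gases": [
            {
                "label": name,
                "sl": {
                    "Tstar": sl.Tstar,
                    "pstar": sl.pstar,
                    "rhostar": sl.rhostar,
                    "molar_mass": sl.molar_mass,
                },
                "pr": {
                    "Tc": GAS_PR[name].Tc,
                    "Pc": GAS_PR[name].Pc,
                    "omega": GAS_PR[name].omega,
                },
            }
            for name, sl in GAS_SL.items()
        ],
        "kij": {
            "gas_gas": KIJ_GAS_GAS,
            "k_pr": K_PR_CO2_CH4,
            "gas_polymer": [
                {"gas": gas_name, "polymer": f"PHBV{hv}", "value": value}
                for (gas_name, hv), value in GAS_POLYMER_KIJ.items()
            ],
        },
        "synthetic": {
            "polymers": ["PHBV0", "PHBV100"],
            "noise_sigma": 0.005,
        },
        "mixing": {
            "endpoints": ["PHBV0", "PHBV100"],
            "x_hv_grid": [0.0, 0.08, 0.16, 0.25, 0.40, 0.60, 0.80, 1.0],
        },
        "sorption": {
            "polymers": ["PHBV8", "PHBV25"],
            "pressures_mpa": [0.1, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
            "compositions": [{"CO2": 0.2, "CH4": 0.8}],
        },
        "sensitivity": {
            "polymers": ["PHBV100"],
            "composition": {"CO2": 0.8, "CH4": 0.2},
            "pressures_mpa": [1.0, 2.0, 3.0],
            "kij_values": [-0.05, -0.01, 0.0, 0.01, 0.05],
        },
    }


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration plus its provenance hash."""

    raw: dict

    @classmethod
    def from_yaml(cls, path):
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise DomainError(f"configuration in {path} must be a mapping")
        return cls(raw)

    @classmethod
    def default(cls):
        return cls(default_config())

    @property
    def config_hash(self):
        """SHA-256 over the canonical JSON form of the configuration.

        The output directory is excluded: it is operational, not
        scientific, so identical configurations produce byte-identical
        tables regardless of where they are written.
        """
        scientific = {k: v for k, v in self.raw.items() if k != "outdir"}
        canonical = json.dumps(scientific, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]

    # -- parsed accessors -------------------------------------------------
    @property
    def seed(self):
        return int(self.raw.get("seed", 0))

    @property
    def outdir(self):
        return Path(self.raw.get("outdir", "slsorb-run"))

    @property
    def temperature(self):
        return float(self.raw.get("temperature", T_SORPTION))

    def gas_entries(self):
        gases = {}
        for entry in self.raw.get("gases", []):
            label = entry["label"]
            sl = entry["sl"]
            gases[label] = {
                "sl": SLParams(
                    float(sl["Tstar"]), float(sl["pstar"]), float(sl["rhostar"]),
                    molar_mass=float(sl["molar_mass"]), label=label,
                ),
                "pr": PRComponent(
                    float(entry["pr"]["Tc"]), float(entry["pr"]["Pc"]),
                    float(entry["pr"]["omega"]), label=label,
                ),
            }
        return gases

    def polymer_entries(self):
        polymers = {}
        for entry in self.raw.get("polymers", []):
            label = entry["label"]
            record = {"hv_mol_percent": float(entry.get("hv_mol_percent", 0.0))}
            if "params" in entry:
                p = entry["params"]
                record["params"] = SLParams.polymer(
                    float(p["Tstar"]), float(p["pstar"]), float(p["rhostar"]), label
                )
            if "pvt_file" in entry:
                pvt = Path(entry["pvt_file"])
                if not pvt.exists():
                    raise DomainError(f"PVT file {pvt} for {label} does not exist")
                record["pvt_file"] = pvt
            if "params" not in record and "pvt_file" not in record:
                raise DomainError(f"polymer {label} needs 'params' or 'pvt_file'")
            polymers[label] = record
        return polymers

    def gas_polymer_kij(self):
        table = {}
        for entry in self.raw.get("kij", {}).get("gas_polymer", []):
            table[(entry["gas"], entry["polymer"])] = float(entry["value"])
        return table

    def validate(self):
        """Cross-reference checks; raises DomainError on inconsistency."""
        gases = self.gas_entries()
        polymers = self.polymer_entries()
        for section in ("sorption", "sensitivity"):
            block = self.raw.get(section) or {}
            for label in block.get("polymers", []):
                if label not in polymers:
                    raise DomainError(f"{section} references unknown polymer {label!r}")
            compositions = block.get("compositions", [])
            if "composition" in block:
                compositions = compositions + [block["composition"]]
            for comp in compositions:
                for gas_name in comp:
                    if gas_name not in gases:
                        raise DomainError(
                            f"{section} references unknown gas {gas_name!r}"
                        )
        return self


def _setup_logging(outdir, log_level):
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    formatter = logging.Formatter(
        fmt="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S%z",
    )
    handler.setFormatter(formatter)
    logger.addHandler(handler)
    logger.setLevel(log_level)
    return handler


def _stage(name, func, summary):
    logger.info("stage %s: start", name)
    try:
        result = func()
    except SlsorbError as exc:
        summary["failed_stage"] = name
        logger.error("stage %s: FAILED: %s", name, exc)
        raise PipelineStageError(name, str(exc)) from exc
    logger.info("stage %s: done", name)
    return result


def _build_system(polymer, gas_records, kij_table, gas_gas, k_pr, temperature):
    gases = tuple(rec["sl"] for rec in gas_records)
    prs = tuple(rec["pr"] for rec in gas_records)
    kij = tuple(
        kij_table.get((g.label, polymer.label), 0.0) for g in gases
    )
    return SorptionSystem(
        polymer=polymer,
        gases=gases,
        kij_gas_polymer=kij,
        kij_gas_gas=gas_gas,
        temperature=temperature,
        pr_components=prs,
        k_pr=k_pr,
    )


def run_pipeline(config, log_level=logging.INFO):
    """Execute the configured workflow; returns the summary dict.

    Stages (each skipped when its configuration block is absent):

    1. ``synthetic`` — generate PVT tables for the named polymers;
    2. ``fit`` — fit SL parameters to every polymer that has a PVT file
       (configured or just generated); polymers with explicit ``params``
       keep them;
    3. ``mixing`` — copolymer parameter trend between two endpoints;
    4. ``sorption`` — pure-gas isotherms per polymer/gas and mixed-gas
       ideal-vs-real selectivity per composition;
    5. ``sensitivity`` — gas-polymer kij sweep.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    the partially written summary marks the failure.
    """
    if isinstance(config, dict):
        config = RunConfig(config)
    config.validate()
    outdir = config.outdir
    handler = _setup_logging(outdir, log_level)
    chash = config.config_hash
    summary = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "tables": [],
    }
    try:
        logger.info("run start: config_hash=%s seed=%d", chash, config.seed)
        gases = config.gas_entries()
        polymers = config.polymer_entries()
        kij_block = config.raw.get("kij", {})
        gas_gas = float(kij_block.get("gas_gas", KIJ_GAS_GAS))
        k_pr = float(kij_block.get("k_pr", K_PR_CO2_CH4))
        kij_table = config.gas_polymer_kij()
        temperature = config.temperature

        def add_table(frame, name):
            path = write_table(frame, outdir / name, chash)
            summary["tables"].append(name)
            return path

        # -- stage: synthetic -------------------------------------------
        synth = config.raw.get("synthetic")
        if synth:
            def do_synthetic():
                for i, label in enumerate(synth.get("polymers", [])):
                    record = polymers[label]
                    if "params" not in record:
                        raise DomainError(
                            f"synthetic stage needs explicit params for {label}"
                        )
                    grid = PVTGridSpec(
                        noise_sigma=float(synth.get("noise_sigma", 0.005)),
                        seed=config.seed + i,
                    )
                    dataset = generate_pvt(
                        record["params"], grid, polymer_id=label,
                        hv_mol_percent=record["hv_mol_percent"],
                    )
                    path = outdir / f"pvt_{label}.csv"
                    write_pvt(dataset, path)
                    summary["tables"].append(path.name)
                    record["pvt_file"] = path
            _stage("synthetic", do_synthetic, summary)

        # -- stage: fit ---------------------------------------------------
        def do_fit():
            rows = []
            for label, record in polymers.items():
                if "pvt_file" not in record:
                    continue
                dataset = read_pvt(
                    record["pvt_file"], polymer_id=label,
                    hv_mol_percent=record["hv_mol_percent"],
                )
                fit = fit_sl_params(dataset)
                record["fitted"] = fit
                if "params" not in record:
                    record["params"] = fit.params
                rows.append(
                    {
                        "polymer": label,
                        "Tstar_K": fit.params.Tstar,
                        "pstar_MPa": fit.params.pstar,
                        "rhostar_g_cm3": fit.params.rhostar,
                        "mape_pct": fit.mape,
                        "r_squared": fit.r_squared,
                        "n_points": fit.n_points,
                        "converged": fit.converged,
                    }
                )
            if rows:
                add_table(pd.DataFrame(rows), "fit_results.csv")
        _stage("fit", do_fit, summary)

        # -- stage: mixing ------------------------------------------------
        mixing = config.raw.get("mixing")
        if mixing:
            def do_mixing():
                hb_label, hv_label = mixing["endpoints"]
                hb = polymers[hb_label]["params"]
                hv = polymers[hv_label]["params"]
                trend = parameter_trend(
                    hb, hv, mixing.get("x_hv_grid", np.linspace(0, 1, 11)),
                    kij=float(mixing.get("kij", 0.0)),
                )
                add_table(trend, "copolymer_trend.csv")
            _stage("mixing", do_mixing, summary)

        # -- stage: sorption ----------------------------------------------
        sorption_block = config.raw.get("sorption")
        if sorption_block:
            def do_sorption():
                pressures = [float(p) for p in sorption_block["pressures_mpa"]]
                gas_records = list(gases.values())
                for label in sorption_block["polymers"]:
                    polymer = polymers[label]["params"]
                    system = _build_system(
                        polymer, gas_records, kij_table, gas_gas, k_pr, temperature
                    )
                    for i, gas_rec in enumerate(gas_records):
                        iso = pure_gas_isotherm(system, i, pressures)
                        add_table(
                            iso, f"isotherm_{label}_{gas_rec['sl'].label}.csv"
                        )
                    if system.n_gases == 2:
                        for comp in sorption_block.get("compositions", []):
                            y0 = float(comp[system.gas_labels[0]])
                            table = mixed_vs_ideal_selectivity(
                                system, pressures, y0
                            )
                            tag = f"{int(round(100 * y0))}"
                            add_table(
                                table, f"selectivity_{label}_y{tag}.csv"
                            )
            _stage("sorption", do_sorption, summary)

        # -- stage: sensitivity --------------------------------------------
        sens = config.raw.get("sensitivity")
        if sens:
            def do_sensitivity():
                pressures = [float(p) for p in sens["pressures_mpa"]]
                kij_values = [float(k) for k in sens.get(
                    "kij_values", (-0.05, -0.01, 0.0, 0.01, 0.05)
                )]
                gas_records = list(gases.values())
                comp = sens.get("composition")
                for label in sens["polymers"]:
                    polymer = polymers[label]["params"]
                    system = _build_system(
                        polymer, gas_records, kij_table, gas_gas, k_pr, temperature
                    )
                    y = None
                    if comp is not None:
                        y = [float(comp[g]) for g in system.gas_labels]
                    sweep = sensitivity_sweep(
                        system, pressures, y, kij_values=kij_values
                    )
                    add_table(sweep, f"sensitivity_{label}.csv")
            _stage("sensitivity", do_sensitivity, summary)

        write_json(summary, outdir / "summary.json")
        logger.info("run complete: %d tables", len(summary["tables"]))
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
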