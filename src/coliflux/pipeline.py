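"""End-to-end orchestration: time series -> rates -> MFA -> balances -> report.

``run_pipeline`` reads a cultivation time series, extracts quasi-steady-state
snapshots on a mu (or time) grid, solves the flux system per snapshot with the
mu-matched biomass composition, and writes delimited result tables plus a run
log.  All stages are importable functions; the CLI in :mod:`coliflux.cli` is
a thin wrapper.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance import CarbonBalance, carbon_balance, wasting_profile
from .biomass import (
    CompositionTable,
    biomass_carbon,
    composition_at_mu,
    default_composition_table,
    drain_fluxes,
    read_composition_table,
)
from .netio import read_network
from .network import MetabolicNetwork, build_default_network
from .rates import (
    CultureTimeSeries,
    SteadyStateSnapshot,
    read_timeseries,
    specific_rates_astat,
    specific_rates_chemostat,
)
from .solver import EnergyLedger, FluxSolution, energy_ledger, solve_fluxes

__all__ = ["RunConfig", "SnapshotResult", "run_pipeline", "analyze_series",
           "compare_snapshots"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    timeseries: str | Path
    out_dir: str | Path
    regime: str = "astat"                     # astat | dstat | chemostat
    composition: str | Path | None = None     # None -> built-in surrogate table
    network: str | Path | None = None         # None -> built-in default network
    snapshot_mu: list[float] = field(default_factory=list)   # astat grid
    snapshot_times: list[float] = field(default_factory=list)  # dstat grid
    window: tuple[float, float] | None = None  # chemostat averaging window
    mode: str = "constraint"                  # constraint | redundancy
    po_ratio: float = 2.0
    seed: int = 0
    derivative_window: int = 11
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "window" in raw and raw["window"] is not None:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.timeseries).exists():
            raise FileNotFoundError(f"time series not found: {self.timeseries}")
        for p in (self.composition, self.network):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        if self.regime not in ("astat", "dstat", "chemostat"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.mode not in ("constraint", "redundancy"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SnapshotResult:
    snapshot: SteadyStateSnapshot
    drains: dict[str, float]
    solution: FluxSolution
    ledger: EnergyLedger
    balance: CarbonBalance


def _snapshots_from_series(
    series: CultureTimeSeries, config: RunConfig
) -> list[SteadyStateSnapshot]:
    if config.regime == "chemostat":
        window = config.window or (
            series.time[0] + 0.75 * (series.time[-1] - series.time[0]),
            series.time[-1],
        )
        return [specific_rates_chemostat(series, window)]
    if config.regime == "dstat":
        times = config.snapshot_times or [
            series.time[0] + 0.75 * (series.time[-1] - series.time[0])
        ]
        return [
            specific_rates_astat(series, t, config.derivative_window)
            for t in times
        ]
    # A-stat: map the mu grid onto times through the dilution-rate ramp
    grid = config.snapshot_mu or list(
        np.round(np.arange(series.dilution_rate[0] + 0.01,
                           series.dilution_rate[-1] - 0.005, 0.02), 4)
    )
    times = np.interp(grid, series.dilution_rate, series.time)
    out = []
    for mu_target, t in zip(grid, times):
        snap = specific_rates_astat(series, float(t), config.derivative_window)
        out.append(snap)
    return out


def analyze_series(
    series: CultureTimeSeries,
    config: RunConfig,
    network: MetabolicNetwork | None = None,
    comp_table: CompositionTable | None = None,
) -> list[SnapshotResult]:
    """Rates -> composition-matched drains -> flux solve -> ledgers, per
    snapshot.  Failures in single snapshots are re-raised with the stage and
    mu attached."""
    net = network or build_default_network()
    if config.po_ratio != net.po_ratio:
        net = net.with_po_ratio(config.po_ratio)
    table = comp_table or default_composition_table()
    results = []
    for snap in _snapshots_from_series(series, config):
        try:
            comp = composition_at_mu(table, snap.mu)
            drains = drain_fluxes(comp, snap.mu, net)
            sol = solve_fluxes(net, snap, drains, mode=config.mode)
            led = energy_ledger(net, sol, drains)
            bal = carbon_balance(snap, biomass_carbon(comp, net), net)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed at mu={snap.mu:.4f}: {exc}"
            ) from exc
        results.append(SnapshotResult(snap, drains, sol, led, bal))
    return results


# ---------------------------------------------------------------------------
# table writers
# ---------------------------------------------------------------------------

def _snapshot_table(results: list[SnapshotResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "mu_per_h": r.snapshot.mu,
            "q_glc_mmol_per_gDCW_h": r.snapshot.q_glc,
            "r_co2_mmol_per_gDCW_h": r.snapshot.r_co2,
            "yield_gDCW_per_g_glc": r.snapshot.biomass_yield,
        }
        for sp, q in sorted(r.snapshot.q_products.items()):
            row[f"q_{sp}_mmol_per_gDCW_h"] = q
        rows.append(row)
    return pd.DataFrame(rows)


def _flux_table(results: list[SnapshotResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for rid, v in r.solution.fluxes.items():
            rows.append(
                {
                    "mu_per_h": r.snapshot.mu,
                    "reaction": rid,
                    "flux_mmol_per_gDCW_h": v,
                    "provenance": r.solution.fixed_mask[rid],
                    "regime": r.solution.regime,
                }
            )
    return pd.DataFrame(rows)


def _ledger_table(results: list[SnapshotResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "mu_per_h": r.snapshot.mu,
                "atp_total_mmol_per_gDCW_h": r.ledger.atp_total,
                "atp_growth_mmol_per_gDCW_h": r.ledger.atp_growth,
                "atp_spilling_mmol_per_gDCW_h": r.ledger.atp_spilling,
                "atp_other_mmol_per_gDCW_h": r.ledger.atp_other,
                "atp_spilling_per_biomass_mmol_per_gDCW":
                    r.ledger.atp_spilling / r.snapshot.mu,
                "frac_atp_glycolysis": r.ledger.frac_atp_glycolysis,
                "frac_co2_tca": r.ledger.frac_co2_tca,
                "frac_nadh_tca": r.ledger.frac_nadh_tca,
            }
        )
    return pd.DataFrame(rows)


def _balance_table(results: list[SnapshotResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "mu_per_h": r.balance.mu,
            "frac_biomass": r.balance.frac_biomass,
            "frac_co2": r.balance.frac_co2,
            "gap": r.balance.gap,
            "total_wasting": r.balance.total_wasting,
        }
        for sp, v in sorted(r.balance.frac_products.items()):
            row[f"frac_{sp}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _make_plots(results: list[SnapshotResult], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mus = [r.snapshot.mu for r in results]
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    axes[0].plot(mus, [r.ledger.atp_spilling for r in results], "o-")
    axes[0].set(xlabel="mu (1/h)", ylabel="ATP spilling (mmol/gDCW/h)")
    axes[1].stackplot(
        mus,
        [r.balance.frac_biomass for r in results],
        [r.balance.frac_co2 for r in results],
        [r.balance.total_wasting for r in results],
        labels=["biomass", "CO2", "wasting"],
    )
    axes[1].legend(loc="lower left", fontsize=7)
    axes[1].set(xlabel="mu (1/h)", ylabel="carbon recovery fraction")
    for sp in ("acetate", "CBASP", "DHO", "orotate", "NAA", "lactate"):
        axes[2].plot(
            mus, [r.balance.frac_products.get(sp, 0.0) for r in results],
            label=sp,
        )
    axes[2].legend(fontsize=7)
    axes[2].set(xlabel="mu (1/h)", ylabel="wasting fraction")
    fig.tight_layout()
    fig.savefig(out / "overview.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run all stages and write the artifact bundle into ``config.out_dir``.

    Returns a map of artifact name -> path.  Reruns with identical config and
    seed produce byte-identical numeric tables.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = read_timeseries(config.timeseries)
    net = read_network(Path(config.network)) if config.network else None
    table = (
        read_composition_table(config.composition) if config.composition else None
    )
    results = analyze_series(series, config, net, table)
    artifacts: dict[str, Path] = {}
    tables = {
        "snapshots": _snapshot_table(results),
        "fluxes": _flux_table(results),
        "energy_ledger": _ledger_table(results),
        "carbon_balance": _balance_table(results),
        "wasting_profile": wasting_profile([r.balance for r in results])
        if len(results) >= 2
        else None,
    }
    for name, df in tables.items():
        if df is None:
            continue
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        artifacts[name] = path
    run_log = {
        "coliflux_version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_snapshots": len(results),
        "worst_balance_residual": max(
            (max(abs(x) for x in r.solution.residuals.values()) for r in results),
            default=0.0,
        ),
        "condition_diagnostics": [r.solution.condition_diagnostic for r in results],
        "regimes": [r.solution.regime for r in results],
        "sign_violations": sorted(
            {rid for r in results for rid in r.solution.sign_violations}
        ),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2, sort_keys=True))
    artifacts["run_log"] = log_path
    if config.make_plots:
        _make_plots(results, out)
        artifacts["overview_plot"] = out / "overview.png"
    for r in results:
        log.info(
            "mu=%.3f regime=%s residual=%.2e cond=%.1f spill=%.3f gap=%.4f",
            r.snapshot.mu, r.solution.regime,
            max(abs(x) for x in r.solution.residuals.values()),
            r.solution.condition_diagnostic,
            r.ledger.atp_spilling, r.balance.gap,
        )
    return artifacts


# ---------------------------------------------------------------------------
# snapshot comparison (A-stat vs chemostat style tables)
# ---------------------------------------------------------------------------

def load_reference_production(kind: str = "chemostat") -> pd.DataFrame:
    """Published per-biomass by-product production levels (mmol/gDCW) for
    glucose-limited E. coli K-12 continuous cultures, as a long-format table
    (mu, species, value).  ``kind``: "chemostat" or "astat"."""
    from importlib.resources import files
    import io as _io

    col = {"chemostat": "chemostat", "astat": "astat_mean"}[kind]
    text = files("coliflux").joinpath("data/byproduct_reference.csv").read_text()
    df = pd.read_csv(_io.StringIO(text), comment="#")
    out = df[["mu", "species", col]].rename(columns={col: "value"})
    return out.dropna(subset=["value"]).reset_index(drop=True)


def production_table(results: list[SnapshotResult]) -> pd.DataFrame:
    """Per-biomass production levels O_x = q_x / mu from pipeline results,
    long format (mu, species, value), for comparison against references."""
    rows = []
    for r in results:
        for sp, o in r.snapshot.per_biomass().items():
            rows.append({"mu": r.snapshot.mu, "species": sp, "value": o})
    return pd.DataFrame(rows)

def compare_snapshots(
    computed: pd.DataFrame,
    reference: pd.DataFrame,
    mu_tol: float = 0.011,
) -> pd.DataFrame:
    """Side-by-side per-species production comparison at matched mu.

    ``computed``: long format with columns (mu, species, value);
    ``reference``: same.  Values are per-biomass production levels
    (mmol/gDCW).  Raises on unmatched mu values.  Output columns:
    mu, species, value_a, value_b, abs_diff, rel_diff.
    """
    rows = []
    for (mu_r, sp), sub in reference.groupby(["mu", "species"]):
        match = computed[
            (computed.species == sp) & (np.abs(computed.mu - mu_r) <= mu_tol)
        ]
        if match.empty:
            raise ValueError(f"no computed value matches mu={mu_r}, {sp}")
        va = float(match.value.iloc[0])
        vb = float(sub.value.iloc[0])
        rows.append(
            {
                "mu": mu_r,
                "species": sp,
                "value_a": va,
                "value_b": vb,
                "abs_diff": va - vb,
                "rel_diff": (va - vb) / vb if vb != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
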