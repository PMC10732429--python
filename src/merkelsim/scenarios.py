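"""Scenario registry: the validation and sweep experiments, one per
published figure panel the model mirrors, with the exact caption values.

Each scenario names its parameter preset, the stimulus protocol, an
optional one-parameter sweep grid, and the horizon.  ``run_scenario``
relaxes the model to rest per grid point (resting levels themselves depend
on pump parameters), runs the protocol, and writes one trace CSV per grid
point plus a combined summary table.  Runs are deterministic: identical
config gives identical CSV output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .constants import to_si
from .errors import MerkelSimError
from .parameters import ModelParameters
from .protocols import ExternalSolution, StimulusProtocol
from .simulator import MerkelCellModel, SolverOptions, summarize_trace

logger = logging.getLogger(__name__)

_PULSE = 114.1e-12  # A; the standard strong rectangular test pulse


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    description: str
    protocol: StimulusProtocol
    horizon: float
    preset: str = "fig2"
    overrides: dict[str, float] = field(default_factory=dict)  # SI
    external: ExternalSolution | None = None
    sweep_param: str | None = None
    sweep_values: tuple[float, ...] = ()   # SI
    sweep_unit: str = ""                   # display unit for labelling

    def grid(self) -> list[tuple[str, dict[str, float]]]:
        """(label, overrides) for every run of the scenario."""
        if self.sweep_param is None:
            return [("base", dict(self.overrides))]
        out = []
        for v in self.sweep_values:
            out.append((f"{self.sweep_param}={v:g}",
                        {**self.overrides, self.sweep_param: v}))
        return out


def _pulse(current_pa: float, duration: float, onset: float = 0.01
           ) -> StimulusProtocol:
    return StimulusProtocol(kind="current_pulse", onset=onset,
                            duration=duration, current=current_pa * 1e-12)


def _compression(depth_um: float, horizon_hold: float = 1e3) -> StimulusProtocol:
    return StimulusProtocol(kind="compression", onset=0.002,
                            duration=horizon_hold, depth=depth_um * 1e-6,
                            ramp_speed=1e-3)


_STORE_BLOCK = {"P_RYR": 0.0, "P_leak_ER": 0.0, "P_IP3": 0.0, "P_pump_ER": 0.0}

_HYPO_EXTERNAL = ExternalSolution(c_na=115.0, c_k=5.0, c_cl=110.0, c_ca=2.0,
                                  c_mannitol=30.0)


def _sweep(name: str, desc: str, param: str, values_printed: tuple[float, ...],
           unit: str, duration: float, horizon: float, preset: str = "fig2"
           ) -> ScenarioSpec:
    return ScenarioSpec(
        name=name, description=desc, preset=preset,
        protocol=_pulse(114.1, duration), horizon=horizon,
        sweep_param=param, sweep_unit=unit,
        sweep_values=tuple(to_si(v, unit) for v in values_printed))


def _registry() -> dict[str, ScenarioSpec]:
    specs = [
        ScenarioSpec(
            name="fig2_negative_pulses",
            description="Passive responses: -8.14 pA current steps, 200 ms.",
            protocol=_pulse(-8.14, 0.2), horizon=0.5,
            sweep_param=None),
        ScenarioSpec(
            name="fig2_positive_pulses",
            description="Peaked depolarisations: 9x and 14x 8.14 pA, 200 ms.",
            protocol=_pulse(9 * 8.14, 0.2), horizon=0.5),
        ScenarioSpec(
            name="fig3_pulses",
            description="Oscillatory phenotype preset, 27.14/54.28/67.85 pA.",
            preset="fig3", protocol=_pulse(54.28, 2.0), horizon=4.0),
        ScenarioSpec(
            name="fig4_highK",
            description="High-K+ swap: +130 mM K, -130 mM Na, 60 s.",
            protocol=StimulusProtocol(kind="high_K", onset=0.5, duration=120.0,
                                      delta_k=130.0, delta_na=-130.0),
            horizon=60.0),
        ScenarioSpec(
            name="fig4_highK_store_blocked",
            description="High-K+ swap with all ER Ca2+ pathways zeroed.",
            protocol=StimulusProtocol(kind="high_K", onset=0.5, duration=120.0,
                                      delta_k=130.0, delta_na=-130.0),
            horizon=60.0, overrides=dict(_STORE_BLOCK)),
        ScenarioSpec(
            name="fig5_hypotonic",
            description="Hypotonic shock: remove 30 mM external mannitol.",
            protocol=StimulusProtocol(kind="hypotonic", onset=0.5,
                                      duration=120.0, delta_mannitol=-30.0),
            horizon=60.0, external=_HYPO_EXTERNAL),
        _sweep("fig6a_gcav12_sweep",
               "Peak-Vm role of Cav1.2: conductance sweep, 200 ms pulse.",
               "g_Cav1_2", (0.0, 2.0, 20.0, 200.0), "mS/cm^2", 0.2, 0.5),
        _sweep("fig6b_gcav21_sweep",
               "Steady-Vm role of Cav2.1: conductance sweep, 200 ms pulse.",
               "g_Cav2_1", (0.0, 0.001, 0.01, 0.1), "mS/cm^2", 0.2, 0.5),
        _sweep("fig6c_pcapump_sweep",
               "Vm oscillation window of the PM Ca pump rate, 200 ms pulse.",
               "P_Capump", (3e-16, 3e-15, 6e-15, 3e-14), "mol/(cm^2 ms)",
               0.2, 0.5),
        _sweep("fig7a_gkv14_sweep",
               "Kv1.4 suppresses the Vm peak: conductance sweep.",
               "g_Kv1_4", (0.0, 0.25, 2.5, 25.0), "mS/cm^2", 0.2, 0.5),
        _sweep("fig7b_gkv42_sweep",
               "Kv4.2 role in Vm: conductance sweep.",
               "g_Kv4_2", (0.0, 0.2, 2.0, 20.0), "mS/cm^2", 0.2, 0.5),
        _sweep("fig7c_gbkca_sweep",
               "BKCa controls the steady Vm; zero conductance lets Vm run "
               "beyond 100 mV.",
               "g_BKCa", (0.0, 0.18, 1.8, 18.0), "mS/cm^2", 0.2, 0.5),
        _sweep("fig7d_gkdr_sweep",
               "KDR role in the steady Vm: conductance sweep.",
               "g_KDR", (0.0, 0.01, 0.1, 1.0), "mS/cm^2", 0.2, 0.5),
        _sweep("fig9a_gcav12_transients",
               "Ca2+-transient role of Cav1.2, 60 s pulse.",
               "g_Cav1_2", (0.0, 0.004, 0.04, 0.4), "mS/cm^2", 60.0, 65.0),
        _sweep("fig9b_gcav21_transients",
               "Ca2+-transient role of Cav2.1, 60 s pulse; the largest "
               "conductance drives Ca2+ beyond 50 uM.",
               "g_Cav2_1", (0.0, 0.2e-4, 0.2e-3, 0.2e-2), "mS/cm^2",
               60.0, 65.0),
        _sweep("fig9c_pcapump_transients",
               "Ca2+-transient role of the PM Ca pump, 60 s pulse.",
               "P_Capump", (0.0, 0.3e-15, 0.3e-14, 0.3e-13),
               "mol/(cm^2 ms)", 60.0, 65.0),
        ScenarioSpec(
            name="fig12_compression",
            description="Ramp-and-hold indentation at 1 um/ms, 100 ms window.",
            protocol=_compression(5.0), horizon=0.1,
            sweep_param="__depth__", sweep_unit="um",
            sweep_values=(3e-6, 4e-6, 5e-6, 6e-6, 7e-6)),
        ScenarioSpec(
            name="fig13_compression_20s",
            description="Ramp-and-hold indentation, 20 s window: sustained "
                        "exocytosis from store-supported Ca2+.",
            protocol=_compression(5.0), horizon=20.0,
            sweep_param="__depth__", sweep_unit="um",
            sweep_values=(3e-6, 4e-6, 5e-6, 6e-6, 7e-6)),
        ScenarioSpec(
            name="suppG_piezo2_knockout",
            description="Indentation with g_Piezo2 = 0: no depolarisation, "
                        "no exocytosis response.",
            protocol=_compression(5.0), horizon=20.0,
            overrides={"g_Piezo2": 0.0}),
    ]
    return {s.name: s for s in specs}


SCENARIOS = _registry()


def list_scenarios() -> list[tuple[str, str]]:
    return [(s.name, s.description) for s in SCENARIOS.values()]


def run_scenario(name: str, out_dir: str | Path,
                 base_params: ModelParameters | None = None,
                 options: SolverOptions | None = None) -> pd.DataFrame:
    """Run a registered scenario; write trace CSV(s) and a summary table.

    Returns the summary DataFrame (one row per grid point).
    """
    try:
        spec = SCENARIOS[name]
    except KeyError:
        raise MerkelSimError(f"unknown scenario {name!r}; see list_scenarios()")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, overrides in _expand(spec):
        params = (base_params or ModelParameters.preset(spec.preset))
        protocol = spec.protocol
        if spec.sweep_param == "__depth__":
            depth = overrides.pop("__depth__")
            protocol = replace(protocol, depth=depth)
        if overrides:
            params = params.replace(**overrides)
        model = MerkelCellModel(params, external=spec.external,
                                options=options)
        logger.info("scenario %s [%s]: relaxing to rest", name, label)
        rest = model.initialize_rest()
        trace = model.run_protocol(rest, protocol, spec.horizon)
        fname = out_dir / f"{name}__{label.replace('=', '_')}.csv"
        trace.to_csv(fname)
        summary = summarize_trace(trace)
        summary["run"] = label
        rows.append(summary)
        logger.info("scenario %s [%s]: peak Vm %.2f mV, peak Ca %.3f uM",
                    name, label, summary["peak_vm_mV"],
                    summary["peak_c_ca_uM"])
    df = pd.DataFrame(rows).set_index("run")
    df.to_csv(out_dir / f"{name}__summary.csv")
    return df


def _expand(spec: ScenarioSpec) -> list[tuple[str, dict[str, float]]]:
    if spec.sweep_param == "__depth__":
        return [(f"d0={v * 1e6:g}um", {**spec.overrides, "__depth__": v})
                for v in spec.sweep_values]
    return spec.grid()
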