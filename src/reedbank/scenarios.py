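"""Scenario runner: each named scenario reproduces one published computation.

Every scenario builds its banks, runs the simulation or solve, applies the
measurement toolkit and returns a bundle of tidy tables plus a dictionary
of derived statistics.  ``run_scenario`` writes the bundle to disk as CSV
files with a JSON sidecar (config echo, statistics, stage log), making
re-runs byte-identical apart from the log timestamps.

A ``scale`` factor in (0, 1] shortens simulated durations and coarsens
frequency grids proportionally for quick smoke runs; 1.0 reproduces the
full protocols (5 s for the 21-reed forced runs, 100 ms forced / 50 ms
impulse for the 201-oscillator runs).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, phasor, timedomain
from .bank import (
    KAPPA_MS2,
    ReedBank,
    build_greenwood_bank,
    build_linear_bank,
    build_wilson_bank,
    gamma_for_kappa,
    tapered_coupling_profile,
)
from .configio import bank_to_config

__all__ = ["Scenario", "run_scenario", "generate_fixture_bank", "SCENARIOS"]

#: Drive frequency of the 201-oscillator forced experiments (Hz).
KHZ_DRIVE = 1750.0


@dataclass(frozen=True)
class Scenario:
    """A named experiment with optional parameter overrides."""

    name: str
    overrides: dict = field(default_factory=dict)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.name!r}; "
                f"choose from {sorted(SCENARIOS)}"
            )
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")


def _khz_bank(kappa_ms2: float, gamma: float = 0.025) -> ReedBank:
    return build_greenwood_bank(kappa=kappa_ms2 * KAPPA_MS2, gamma=gamma)


def _profile_frame(bank: ReedBank, amp, phase, label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": label,
            "reed_index": np.arange(1, bank.n + 1),
            "natural_freq_hz": bank.natural_freq_hz,
            "amplitude": amp,
            "phase_cycles": phase,
        }
    )


def _scn_switch_on(p: dict, scale: float):
    """Switch-on transient of the 21-reed bank driven at 50 Hz."""
    kappa = p.get("kappa", 2500.0)
    gamma = p.get("gamma", 0.014)
    duration = p.get("duration_s", 5.0) * scale
    bank = build_wilson_bank(kappa, gamma)
    drive = timedomain.DriveSpec(p.get("drive_hz", 50.0), duration)
    traj = timedomain.simulate_forced(bank, drive)
    settle = timedomain.settling_time(traj)
    watch = [0, 10, 20]  # 55, 50 and 45 Hz reeds
    tables = {
        "transients": pd.DataFrame(
            {"time_s": traj.time_s}
            | {
                f"reed_{j + 1}_{bank.natural_freq_hz[j]:g}Hz":
                    traj.displacement[j]
                for j in watch
            }
        ),
        "settling": pd.DataFrame(
            {
                "reed_index": np.arange(1, bank.n + 1),
                "natural_freq_hz": bank.natural_freq_hz,
                "settling_time_s": settle,
            }
        ),
    }
    stats = {
        "max_settling_time_s": float(np.max(settle)),
        "all_settled_by_2s": bool(np.max(settle) <= 2.0),
    }
    return bank, tables, stats


def _scn_waterfall(p: dict, scale: float):
    """Traveling-wave waterfall: last 2 cycles, coupled vs uncoupled."""
    gamma = p.get("gamma", 0.014)
    duration = p.get("duration_s", 5.0) * scale
    drive = timedomain.DriveSpec(p.get("drive_hz", 50.0), duration)
    tables, stats = {}, {}
    for label, kappa in (("uncoupled", 0.0), ("coupled", p.get("kappa", 2500.0))):
        bank = build_wilson_bank(kappa, gamma)
        traj = timedomain.simulate_forced(bank, drive)
        n_keep = 2 * round(1.0 / (drive.freq_hz * traj.dt))
        sl = slice(traj.time_s.size - n_keep - 1, traj.time_s.size)
        frame = pd.DataFrame(
            traj.displacement[:, sl].T,
            columns=[f"reed_{j + 1}" for j in range(bank.n)],
        )
        frame.insert(0, "time_s", traj.time_s[sl])
        tables[f"waterfall_{label}"] = frame
    bank = build_wilson_bank(p.get("kappa", 2500.0), gamma)
    return bank, tables, stats


def _scn_coupling_sweep(p: dict, scale: float):
    """Amplitude/phase profiles over the damping-calibrated coupling sweep."""
    kappas = p.get("kappas", list(range(0, 5001, 100)))
    drive_hz = p.get("drive_hz", 50.0)
    rows = []
    for kappa in kappas:
        bank = build_wilson_bank(kappa, gamma_for_kappa(kappa))
        resp = phasor.solve_phasors(bank, drive_hz)
        amp = resp.amplitude
        rows.append(
            _profile_frame(
                bank, amp / amp.max(), resp.phase_relative_to(0),
                f"kappa={kappa:g}",
            ).assign(kappa=kappa, gamma=bank.gamma)
        )
    profiles = pd.concat(rows, ignore_index=True)
    lag = {
        kappa: float(
            profiles.loc[profiles["kappa"] == kappa, "phase_cycles"].iloc[-1]
        )
        for kappa in kappas
    }
    stats = {
        "n_combinations": len(kappas),
        "total_lag_cycles_by_kappa": {str(k): v for k, v in lag.items()},
    }
    bank = build_wilson_bank(kappas[-1], gamma_for_kappa(kappas[-1]))
    return bank, {"profiles": profiles}, stats


def _scn_reed_tuning(p: dict, scale: float):
    """Frequency response of each of the 21 reeds across a drive sweep."""
    kappa = p.get("kappa", 2200.0)
    gamma = p.get("gamma", 0.013)
    step = p.get("grid_step_hz", 0.1) / scale
    grid = np.arange(p.get("f_lo_hz", 40.0), p.get("f_hi_hz", 60.0) + step / 2,
                     step)
    bank = build_wilson_bank(kappa, gamma)
    rmap = phasor.response_map(bank, grid)
    best = rmap.drive_freq_hz[np.argmax(rmap.amplitude, axis=0)]
    tables = {
        "response_map": rmap.to_frame().reset_index(),
        "best_drive": pd.DataFrame(
            {
                "reed_index": np.arange(1, bank.n + 1),
                "natural_freq_hz": bank.natural_freq_hz,
                "best_drive_hz": best,
            }
        ),
    }
    interior = slice(1, -1)
    stats = {
        "peak_above_natural_all_reeds": bool(
            np.all(best[interior] > bank.natural_freq_hz[interior])
        ),
    }
    return bank, tables, stats


def _scn_spatial_ripples(p: dict, scale: float):
    """201-oscillator spatial profiles at 1.75 kHz over a coupling sweep."""
    kappas = p.get("kappas_ms2", list(range(0, 401, 10)))
    drive_hz = p.get("drive_hz", KHZ_DRIVE)
    rows = []
    for kappa in kappas:
        bank = _khz_bank(kappa, p.get("gamma", 0.025))
        resp = phasor.solve_phasors(bank, drive_hz)
        rows.append(
            _profile_frame(
                bank, resp.amplitude, resp.phase_lag_cycles, f"kappa={kappa:g}"
            ).assign(kappa=kappa)
        )
    profiles = pd.concat(rows, ignore_index=True)
    bank = _khz_bank(kappas[-1])
    peak_freq = {}
    for kappa in kappas:
        sub = profiles[profiles["kappa"] == kappa]
        peak_freq[str(kappa)] = float(
            sub["natural_freq_hz"].iloc[int(np.argmax(sub["amplitude"]))]
        )
    return bank, {"profiles": profiles}, {"peak_natural_freq_hz": peak_freq}


def _scn_response_map(p: dict, scale: float):
    """2-D response of the 201-oscillator bank, 1-2.5 kHz drive grid."""
    kappa = p.get("kappa_ms2", 200.0)
    step = p.get("grid_step_hz", 2.5) / scale
    grid = np.arange(p.get("f_lo_hz", 1000.0),
                     p.get("f_hi_hz", 2500.0) + step / 2, step)
    bank = _khz_bank(kappa, p.get("gamma", 0.025))
    rmap = phasor.response_map(bank, grid)
    spatial = rmap.spatial_transect(KHZ_DRIVE)
    ps_spatial = analysis.find_peaks(spatial, bank.natural_freq_hz,
                                     min_prominence_db=0.5)
    rat_spatial = analysis.peak_ratios(ps_spatial)
    freq_cut = rmap.frequency_transect(KHZ_DRIVE)
    ps_freq = analysis.find_peaks(freq_cut, rmap.drive_freq_hz,
                                  min_prominence_db=0.5)
    rat_freq = analysis.peak_ratios(ps_freq)
    stats = {
        "spatial_peak_locations_hz": ps_spatial.location.tolist(),
        "spatial_peak_ratios": rat_spatial.tolist(),
        "main_secondary_ratio_spatial": float(rat_spatial[-1]),
        "ripple_ratio_mean_spatial": float(np.mean(rat_spatial[:-1])),
        "frequency_transect_peak_ratios": rat_freq.tolist(),
    }
    return bank, {"response_map": rmap.to_frame().reset_index()}, stats


def _scn_phase_transitions(p: dict, scale: float):
    """Amplitude minima vs rapid phase transitions at 1.8 kHz drive."""
    drive_hz = p.get("drive_hz", 1800.0)
    rows = []
    for kappa in p.get("kappas_ms2", [200.0, 500.0]):
        bank = _khz_bank(kappa, p.get("gamma", 0.025))
        resp = phasor.solve_phasors(bank, drive_hz)
        rows.append(
            _profile_frame(
                bank, resp.amplitude, resp.phase_lag_cycles, f"kappa={kappa:g}"
            ).assign(kappa=kappa)
        )
    bank = _khz_bank(200.0)
    return bank, {"profiles": pd.concat(rows, ignore_index=True)}, {}


def _scn_boundary_taper(p: dict, scale: float):
    """Uniform vs end-tapered coupling: the ripples are not edge reflections."""
    from dataclasses import replace

    drive_hz = p.get("drive_hz", KHZ_DRIVE)
    margin = p.get("edge_margin", 20)
    rows, stats = [], {}
    for kappa in p.get("kappas_ms2", [200.0, 400.0]):
        uniform = _khz_bank(kappa, p.get("gamma", 0.025))
        tapered = replace(
            uniform,
            coupling=tapered_coupling_profile(
                uniform.n, kappa * KAPPA_MS2, p.get("ramp_links", 10)
            ),
        )
        ru = phasor.solve_phasors(uniform, drive_hz)
        rt = phasor.solve_phasors(tapered, drive_hz)
        diff_db = 20.0 * np.log10(rt.amplitude / ru.amplitude)
        rows.append(
            pd.DataFrame(
                {
                    "kappa": kappa,
                    "reed_index": np.arange(1, uniform.n + 1),
                    "natural_freq_hz": uniform.natural_freq_hz,
                    "amplitude_uniform": ru.amplitude,
                    "amplitude_tapered": rt.amplitude,
                    "difference_db": diff_db,
                }
            )
        )
        stats[f"max_mid_array_difference_db_kappa{kappa:g}"] = float(
            np.max(np.abs(diff_db[margin:-margin]))
        )
    bank = _khz_bank(200.0)
    return bank, {"taper_comparison": pd.concat(rows, ignore_index=True)}, stats


def _scn_single_reed(p: dict, scale: float):
    """Drive one reed only; measure attenuation away from it."""
    kappa = p.get("kappa_ms2", 200.0)
    drive_hz = p.get("drive_hz", KHZ_DRIVE)
    bank = _khz_bank(kappa, p.get("gamma", 0.025))
    j = int(np.argmin(np.abs(bank.natural_freq_hz - drive_hz)))
    all_resp = phasor.solve_phasors(bank, drive_hz)
    one_resp = phasor.single_reed_drive(bank, j, drive_hz)
    low, high = analysis.attenuation_slopes(one_resp, j)
    tables = {
        "responses": pd.DataFrame(
            {
                "reed_index": np.arange(1, bank.n + 1),
                "natural_freq_hz": bank.natural_freq_hz,
                "amplitude_all_driven": all_resp.amplitude,
                "amplitude_single_driven": one_resp.amplitude,
            }
        )
    }
    stats = {
        "driven_reed_index": j + 1,
        "driven_reed_natural_freq_hz": float(bank.natural_freq_hz[j]),
        "low_side_attenuation_db_per_oct": low,
        "high_side_attenuation_db_per_oct": high,
    }
    return bank, tables, stats


def _scn_phase_bands(p: dict, scale: float):
    """Spatial phase bands of the forced 201-oscillator bank (time domain)."""
    drive_hz = p.get("drive_hz", KHZ_DRIVE)
    duration = p.get("duration_s", 0.1) * scale
    rows, stats = [], {}
    for kappa in p.get("kappas_ms2", [0.0, 200.0, 400.0]):
        bank = _khz_bank(kappa, p.get("gamma", 0.025))
        traj = timedomain.simulate_forced(
            bank, timedomain.DriveSpec(drive_hz, duration)
        )
        prof = timedomain.steady_state_profile(traj)
        rows.append(
            _profile_frame(
                bank, prof.amplitude, prof.phase_cycles, f"kappa={kappa:g}"
            ).assign(kappa=kappa)
        )
        if kappa > 0:
            stats[f"band_period_hz_kappa{kappa:g}"] = analysis.phase_band_period(
                prof
            )
    bank = _khz_bank(200.0)
    return bank, {"profiles": pd.concat(rows, ignore_index=True)}, stats


def _scn_impulse_spectra(p: dict, scale: float):
    """Impulse responses of the Greenwood bank and their spectra."""
    kappa = p.get("kappa_ms2", 200.0)
    duration = p.get("duration_s", 0.05) * scale
    bank = _khz_bank(kappa, p.get("gamma", 0.025))
    traj = timedomain.simulate_impulse(bank, duration)
    spec = analysis.impulse_spectrum(traj)
    watch = p.get("reeds", list(range(1, bank.n + 1, 20)))
    ratios_first, rows = [], []
    for reed in range(60, 141, 10):
        ps = analysis.find_peaks(
            spec.magnitude[reed], spec.freq_hz, min_prominence_db=1.0,
            floor_db=40.0,
        )
        rr = analysis.peak_ratios(ps)
        if rr.size:
            ratios_first.append(rr[0])
    for reed in watch:
        rows.append(
            pd.DataFrame(
                {
                    "reed_index": reed,
                    "freq_hz": spec.freq_hz,
                    "magnitude": spec.magnitude[reed - 1],
                }
            )
        )
    tables = {
        "impulse_sample": pd.DataFrame(
            {"time_s": traj.time_s}
            | {f"reed_{r}": traj.displacement[r - 1] for r in watch}
        ),
        "spectra": pd.concat(rows, ignore_index=True),
    }
    stats = {
        "first_spacing_ratio_mean": float(np.mean(ratios_first)),
        "first_spacing_ratio_per_reed": [float(r) for r in ratios_first],
    }
    return bank, tables, stats


def _scn_plateaus(p: dict, scale: float):
    """Frequency-plateau clustering on the equally spaced 1-2 kHz bank."""
    duration = p.get("duration_s", 0.05) * scale
    gamma = p.get("gamma", 0.025)
    rows, stats = [], {}
    for kappa in p.get("kappas_ms2", [0.0, 1000.0]):
        bank = build_linear_bank(1000.0, 2000.0, 201, kappa * KAPPA_MS2, gamma)
        traj = timedomain.simulate_impulse(bank, duration)
        spec = analysis.impulse_spectrum(traj)
        pmap = analysis.dominant_frequency_map(spec)
        rows.append(
            pd.DataFrame(
                {
                    "kappa": kappa,
                    "reed_index": np.arange(1, bank.n + 1),
                    "natural_freq_hz": bank.natural_freq_hz,
                    "dominant_freq_hz": pmap.dominant_freq_hz,
                }
            )
        )
        if kappa > 0:
            vals = analysis.plateau_values(pmap)
            ratios = analysis.plateau_ratios(pmap)
            stats[f"plateau_values_hz_kappa{kappa:g}"] = vals.tolist()
            stats[f"plateau_ratios_kappa{kappa:g}"] = ratios.tolist()
    bank = build_linear_bank(1000.0, 2000.0, 201, 1000.0 * KAPPA_MS2, gamma)
    return bank, {"dominant_frequency_map": pd.concat(rows, ignore_index=True)}, stats


SCENARIOS = {
    "switch_on": _scn_switch_on,
    "waterfall": _scn_waterfall,
    "coupling_sweep": _scn_coupling_sweep,
    "reed_tuning": _scn_reed_tuning,
    "spatial_ripples": _scn_spatial_ripples,
    "response_map": _scn_response_map,
    "phase_transitions": _scn_phase_transitions,
    "boundary_taper": _scn_boundary_taper,
    "single_reed": _scn_single_reed,
    "phase_bands": _scn_phase_bands,
    "impulse_spectra": _scn_impulse_spectra,
    "plateaus": _scn_plateaus,
}

#: Figure-style aliases for the scenario names.
ALIASES = {
    "fig3": "switch_on",
    "fig4": "waterfall",
    "fig5_6": "coupling_sweep",
    "fig7": "reed_tuning",
    "fig8": "spatial_ripples",
    "fig9": "response_map",
    "fig10": "phase_transitions",
    "fig11": "boundary_taper",
    "fig12": "single_reed",
    "fig13": "phase_bands",
    "fig14": "impulse_spectra",
    "fig15": "plateaus",
}


def run_scenario(scenario: Scenario, outdir: str | Path | None = None) -> dict:
    """Execute a scenario; optionally write its output bundle.

    Returns ``{"tables": {name: DataFrame}, "stats": {...}, "meta": {...}}``.
    When ``outdir`` is given, each table is written as CSV and the stats,
    config echo and stage log as ``<name>_meta.json``.
    """
    name = ALIASES.get(scenario.name, scenario.name)
    func = SCENARIOS[name]
    t0 = time.perf_counter()
    bank, tables, stats = func(dict(scenario.overrides), scenario.scale)
    elapsed = time.perf_counter() - t0
    from . import __version__

    meta = {
        "scenario": name,
        "overrides": scenario.overrides,
        "scale": scenario.scale,
        "bank": bank_to_config(bank),
        "stats": stats,
        "code_version": __version__,
        "log": [{"stage": name, "wall_time_s": round(elapsed, 3),
                 "tables": sorted(tables)}],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tname, frame in tables.items():
            frame.to_csv(outdir / f"{name}_{tname}.csv", index=False,
                         float_format="%.12g")
        (outdir / f"{name}_meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )
    return {"tables": tables, "stats": stats, "meta": meta}


def generate_fixture_bank(
    seed: int,
    n_range: tuple[int, int] = (3, 12),
    f_range: tuple[float, float] = (40.0, 60.0),
    kappa_range: tuple[float, float] = (0.0, 5000.0),
    gamma_range: tuple[float, float] = (0.005, 0.05),
) -> ReedBank:
    """Reproducible random bank for property tests."""
    if n_range[0] < 2 or n_range[1] < n_range[0]:
        raise ValueError("degenerate n_range")
    if f_range[0] <= 0 or f_range[1] < f_range[0]:
        raise ValueError("degenerate f_range")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    freqs = np.sort(rng.uniform(*f_range, size=n))[::-1]
    freqs += np.arange(n)[::-1] * 1e-6  # guard against exact ties
    return ReedBank(
        natural_freq_hz=freqs,
        gamma=float(rng.uniform(*gamma_range)),
        coupling=rng.uniform(*kappa_range, size=n - 1),
        f0=1000.0,
    )
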