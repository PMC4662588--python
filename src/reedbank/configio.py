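"""Serialization of bank definitions and analysis outputs.

Bank configurations round-trip through flat-key YAML so that every
experiment can be reproduced from a small text file.  Two forms are
supported: builder form (``bank_type`` plus the builder's parameters) and
explicit form (the full frequency/coupling vectors), the latter used for
banks that no builder produces.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import bank as _bank
from .bank import ReedBank

__all__ = ["bank_to_config", "bank_from_config", "save_bank", "load_bank",
           "export_bank_csv"]

_BUILDERS = {
    "wilson": _bank.build_wilson_bank,
    "greenwood": _bank.build_greenwood_bank,
    "linear": _bank.build_linear_bank,
}


def bank_to_config(bank: ReedBank) -> dict:
    """Explicit-form configuration dictionary for any bank."""
    cfg = {
        "bank_type": "explicit",
        "natural_freq_hz": [float(f) for f in bank.natural_freq_hz],
        "gamma": float(bank.gamma),
        "f0": float(bank.f0),
    }
    kap = bank.coupling
    if np.all(kap == kap[0]):
        cfg["kappa"] = float(kap[0])
    else:
        cfg["coupling"] = [float(k) for k in kap]
    mask = bank.forcing_mask
    if np.all(mask == 1.0):
        cfg["forcing"] = "all"
    elif np.count_nonzero(mask) == 1 and mask.max() == 1.0:
        cfg["forcing"] = f"reed:{int(np.argmax(mask)) + 1}"
    else:
        cfg["forcing_mask"] = [float(m) for m in mask]
    return cfg


def _apply_forcing(bank: ReedBank, cfg: dict) -> ReedBank:
    if "forcing_mask" in cfg:
        return bank.with_forcing_mask(np.asarray(cfg["forcing_mask"], float))
    forcing = cfg.get("forcing", "all")
    if forcing == "all":
        return bank
    if isinstance(forcing, str) and forcing.startswith("reed:"):
        return bank.with_single_reed_forcing(int(forcing.split(":")[1]) - 1)
    raise ValueError(f"unknown forcing spec {forcing!r}")


def bank_from_config(cfg: dict) -> ReedBank:
    """Build a bank from a flat configuration dictionary."""
    cfg = dict(cfg)
    kind = cfg.pop("bank_type", "explicit")
    forcing_keys = {k: cfg.pop(k) for k in ("forcing", "forcing_mask")
                    if k in cfg}
    taper = cfg.pop("taper_ramp_links", None)
    if kind == "explicit":
        coupling = (cfg.pop("coupling") if "coupling" in cfg
                    else cfg.pop("kappa"))
        b = ReedBank(
            natural_freq_hz=np.asarray(cfg.pop("natural_freq_hz"), float),
            gamma=float(cfg.pop("gamma")),
            coupling=np.asarray(coupling, float),
            f0=float(cfg.pop("f0", 1000.0)),
        )
    elif kind in _BUILDERS:
        b = _BUILDERS[kind](**cfg)
    else:
        raise ValueError(f"unknown bank_type {kind!r}")
    if taper is not None:
        kap_max = float(np.max(b.coupling))
        from dataclasses import replace

        b = replace(
            b,
            coupling=_bank.tapered_coupling_profile(b.n, kap_max, int(taper)),
        )
    return _apply_forcing(b, forcing_keys)


def save_bank(bank: ReedBank, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(bank_to_config(bank), sort_keys=False))


def load_bank(path: str | Path) -> ReedBank:
    return bank_from_config(yaml.safe_load(Path(path).read_text()))


def export_bank_csv(bank: ReedBank, path: str | Path) -> None:
    """Per-reed CSV: index, natural frequency, left/right link coupling."""
    bank.to_frame().to_csv(path, index=False)
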