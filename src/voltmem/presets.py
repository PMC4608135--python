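"""Packaged ionic-condition presets and channel fixtures.

Two condition presets ship with the package — an amphibian (Xenopus) oocyte
preparation at 23 degC and a standard mammalian preparation at 36 degC — as
editable YAML tables of per-ion gradients.  Channel fixtures ship in the
same ChannelML-dialect schema the reader consumes, so loading a fixture and
loading user XML are the same code path.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import yaml

from .channelml import read_channelml
from .errors import VoltmemError
from .kinetics import ChannelModel
from .membrane import IonicConditions, IonRecord

__all__ = [
    "load_conditions",
    "load_channel",
    "builtin_condition_names",
    "builtin_channel_names",
]

_CONDITION_FILES = {"amphibian": "amphibian.yaml", "mammalian": "mammalian.yaml"}
_CHANNEL_FILES = {
    "nav16_reduced": "nav16_reduced.xml",
    "kir_synthetic": "kir_synthetic.xml",
    "slow_inward_synthetic": "slow_inward_synthetic.xml",
}


def _data_path(filename: str) -> Path:
    return Path(resources.files("voltmem") / "data" / filename)


def builtin_condition_names() -> list[str]:
    return sorted(_CONDITION_FILES)


def builtin_channel_names() -> list[str]:
    return sorted(_CHANNEL_FILES)


def conditions_from_dict(doc: dict) -> IonicConditions:
    ions = {
        sp: IonRecord(
            intracellular_mm=float(rec["intracellular_mm"]),
            extracellular_mm=float(rec["extracellular_mm"]),
            valence=int(rec["valence"]),
        )
        for sp, rec in doc["ions"].items()
    }
    return IonicConditions(
        name=str(doc["name"]),
        temperature_c=float(doc["temperature_c"]),
        ions=ions,
        fixed_reversals_mv={k: float(v) for k, v in doc.get("fixed_reversals_mv", {}).items()},
        leak_species=str(doc.get("leak_species", "Cl")),
    )


def load_conditions(name_or_path: str) -> IonicConditions:
    """Load a condition preset by name ('amphibian', 'mammalian') or YAML path."""
    if name_or_path in _CONDITION_FILES:
        path = _data_path(_CONDITION_FILES[name_or_path])
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise VoltmemError(
                f"unknown conditions {name_or_path!r}; built-ins: "
                f"{', '.join(builtin_condition_names())}"
            )
    with open(path) as fh:
        return conditions_from_dict(yaml.safe_load(fh))


def load_channel(name_or_path: str) -> ChannelModel:
    """Load a channel fixture by name or any ChannelML-subset XML path."""
    if name_or_path in _CHANNEL_FILES:
        return read_channelml(str(_data_path(_CHANNEL_FILES[name_or_path])))
    path = Path(name_or_path)
    if not path.exists():
        raise VoltmemError(
            f"unknown channel {name_or_path!r}; built-ins: "
            f"{', '.join(builtin_channel_names())}"
        )
    return read_channelml(str(path))
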