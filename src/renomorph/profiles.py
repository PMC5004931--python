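"""Loading and saving stain-profile configurations (YAML)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .color import StainProfile

__all__ = ["load_profiles", "save_profiles", "default_profiles"]


def load_profiles(path: str | Path) -> dict[str, StainProfile]:
    """Read a YAML mapping of stain name -> profile parameters."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"profile file {path} must contain a mapping")
    return {name: StainProfile.from_dict(name, params) for name, params in raw.items()}


def save_profiles(profiles: dict[str, StainProfile], path: str | Path) -> None:
    raw = {name: p.to_dict() for name, p in profiles.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_profiles() -> dict[str, StainProfile]:
    """The shipped profiles: trichrome blue/red, PAS, and DAB-based IHC.

    DAB parameters are shared by the collagen III, cytokeratin and CD34
    entries so each stain image can be quantified by name.
    """
    ref = resources.files("renomorph.data").joinpath("default_profiles.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {name: StainProfile.from_dict(name, params) for name, params in raw.items()}
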