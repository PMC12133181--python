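"""Loading cross designs from YAML and the built-in design registry."""

from __future__ import annotations

from importlib import resources

import yaml

from .karyotype import CrossDesign, Genotype

__all__ = ["load_designs", "builtin_designs", "get_design"]


def _parse_design(name: str, spec: dict) -> CrossDesign:
    try:
        mother = Genotype(xs=spec["mother"].get("xs", []),
                          ys=spec["mother"].get("ys", []))
        father = Genotype(xs=spec["father"].get("xs", []),
                          ys=spec["father"].get("ys", []))
        class_map = dict(spec["classes"])
    except KeyError as e:
        raise ValueError(f"design {name!r}: missing field {e}") from None
    return CrossDesign(
        name=name,
        mother=mother,
        father=father,
        class_map=class_map,
        unscored=tuple(spec.get("unscored", ())),
        description=spec.get("description", ""),
    )


def load_designs(path_or_stream) -> dict:
    """Parse a YAML mapping of design name -> design spec."""
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("design file must be a mapping of name -> spec")
    return {name: _parse_design(name, spec) for name, spec in raw.items()}


def builtin_designs() -> dict:
    """The designs shipped with the package."""
    text = resources.files("karyodyn.data").joinpath("designs.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: _parse_design(name, spec) for name, spec in raw.items()}


def get_design(name: str) -> CrossDesign:
    designs = builtin_designs()
    try:
        return designs[name]
    except KeyError:
        raise KeyError(
            f"unknown design {name!r}; built-ins: {', '.join(sorted(designs))}"
        ) from None
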