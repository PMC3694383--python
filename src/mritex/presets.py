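"""Body-region parameter presets for the eight texture operators.

Each region (brain, heart, liver, bone) carries, per operator family, the
grid of exponent/base/radius values found useful for segmentation in that
region.  ``default_ops`` picks one deterministic configuration per family:
n1 = 1 and n2 = 2 (the values that almost always separate background from
informative content), and for the second-order families the first listed
value of each exponent with radius d = 2 where the grid offers it (the
radius most often adequate), otherwise the first listed radius.
"""

from __future__ import annotations

from .second_order import OperatorSpec

__all__ = ["PRESET_GRIDS", "REGIONS", "default_ops", "grid_ops"]

REGIONS = ("brain", "heart", "liver", "bone")

PRESET_GRIDS: dict = {
    "brain": {
        "M": {"n1": [1, 2]},
        "C": {"n2": [2, 3]},
        "HG": {"n3": [2, 3], "d": [1, 2, 3, 4]},
        "CT": {"n4": [2, 3], "n5": [1, 2], "d": [1, 2, 3, 4]},
        "ID": {"n6": [1, 2, 3], "n7": [2], "d": [1, 2, 3, 4]},
        "ET": {"n8": [1, 2], "n9": [1, 2], "k1": [2], "d": [1, 2, 3, 4]},
        "CR": {"n10": [1, 2, 3], "n11": [1, 3], "d": [1, 3]},
        "DE": {"n12": [2, 3, 4], "n13": [2, 4], "k2": [2], "d": [2, 4]},
    },
    "heart": {
        "M": {"n1": [1, 2]},
        "C": {"n2": [2, 3]},
        "HG": {"n3": [2, 3], "d": [1, 2, 3, 4]},
        "CT": {"n4": [2, 3], "n5": [1, 2], "d": [1, 2, 3, 4]},
        "ID": {"n6": [2, 3], "n7": [2], "d": [2, 4]},
        "ET": {"n8": [2, 3], "n9": [2], "k1": [2], "d": [2, 4]},
        "CR": {"n10": [1, 3], "n11": [2, 3], "d": [1, 2, 4]},
        "DE": {"n12": [1, 4], "n13": [2, 4], "k2": [2], "d": [1, 2, 4]},
    },
    "liver": {
        "M": {"n1": [1, 2]},
        "C": {"n2": [2, 3]},
        "HG": {"n3": [2, 3, 4], "d": [1, 2, 3, 4]},
        "CT": {"n4": [2, 3], "n5": [1, 2], "d": [1, 2, 3, 4]},
        "ID": {"n6": [1, 3], "n7": [3], "d": [1, 2, 3, 4]},
        "ET": {"n8": [1, 2, 3], "n9": [3], "k1": [2], "d": [2, 3, 4]},
        "CR": {"n10": [2, 4], "n11": [3], "d": [1, 2, 4, 6]},
        "DE": {"n12": [1, 4], "n13": [2], "k2": [2], "d": [1, 2, 3, 4]},
    },
    "bone": {
        "M": {"n1": [1, 2]},
        "C": {"n2": [2, 3, 4]},
        "HG": {"n3": [2, 3, 4], "d": [2, 4, 6]},
        "CT": {"n4": [2, 3], "n5": [2], "d": [2, 3, 4]},
        "ID": {"n6": [1, 3], "n7": [2], "d": [2, 3, 4]},
        "ET": {"n8": [2, 3, 4], "n9": [3], "k1": [2], "d": [2, 4]},
        "CR": {"n10": [2, 4], "n11": [2, 4, 6], "d": [2, 4]},
        "DE": {"n12": [3], "n13": [3], "k2": [2], "d": [2, 4]},
    },
}

_DEFAULT_FIRST = {"n1": 1, "n2": 2}


def _default_for(name: str, grid: dict) -> OperatorSpec:
    params = {}
    d = None
    for key, values in grid.items():
        if key == "d":
            d = 2 if 2 in values else values[0]
        elif key in _DEFAULT_FIRST and _DEFAULT_FIRST[key] in values:
            params[key] = _DEFAULT_FIRST[key]
        else:
            params[key] = values[0]
    return OperatorSpec(name, params, d=d)


def default_ops(region: str = "brain") -> list[OperatorSpec]:
    """One deterministic OperatorSpec per family for a body-region preset."""
    if region not in PRESET_GRIDS:
        raise ValueError(f"unknown preset {region!r}; choose from {REGIONS}")
    grids = PRESET_GRIDS[region]
    return [_default_for(name, grids[name]) for name in grids]


def grid_ops(region: str) -> dict[str, list[OperatorSpec]]:
    """Every candidate OperatorSpec per family, in deterministic grid order."""
    if region not in PRESET_GRIDS:
        raise ValueError(f"unknown preset {region!r}; choose from {REGIONS}")
    out: dict[str, list[OperatorSpec]] = {}
    for name, grid in PRESET_GRIDS[region].items():
        keys = [k for k in grid if k != "d"]
        ds = grid.get("d", [None])
        combos: list[dict] = [{}]
        for k in keys:
            combos = [dict(c, **{k: v}) for c in combos for v in grid[k]]
        specs = []
        for d in ds:
            for c in combos:
                specs.append(OperatorSpec(name, c, d=d))
        out[name] = specs
    return out
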