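"""Canonical cortical region sets.

Nodes of every covariance network are cortical regions from a fixed,
ordered parcellation.  The packaged default is the 68-region Desikan-Killiany
gyral atlas (34 regions per hemisphere).  Order is fixed as left-hemisphere
regions first, then right, each block alphabetical by region name, and is
stable across the whole pipeline: correlation-matrix rows, graph node ids
and nodal-metric tables all follow it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import ValidationError

#: accepted hemisphere spellings, normalized to lh/rh
_HEMI_CODES = {
    "lh": "lh",
    "rh": "rh",
    "left": "lh",
    "right": "rh",
    "l": "lh",
    "r": "rh",
}

_DEFAULT_TABLE = "desikan_regions.tsv"


@dataclass(frozen=True)
class RegionSet:
    """Ordered set of cortical regions defining the network node identity.

    Parameters
    ----------
    names
        Bare region names (e.g. ``"bankssts"``), aligned with ``hemispheres``.
    hemispheres
        ``"lh"`` or ``"rh"`` per region.
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.hemispheres):
            raise ValidationError("names and hemispheres differ in length")
        if len(self.names) == 0:
            raise ValidationError("region set is empty")
        bad = [h for h in self.hemispheres if h not in ("lh", "rh")]
        if bad:
            raise ValidationError(f"unknown hemisphere code(s): {sorted(set(bad))}")
        labels = self.labels
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate region(s): {dupes}")

    @property
    def labels(self) -> tuple[str, ...]:
        """Fully qualified labels, e.g. ``"lh_bankssts"``."""
        return tuple(f"{h}_{n}" for n, h in zip(self.names, self.hemispheres))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.hemispheres))

    @property
    def size(self) -> int:
        return len(self.names)


def load_region_table(path: str | None = None) -> RegionSet:
    """Load an ordered region set from a two-column TSV (``name``, ``hemisphere``).

    With ``path=None`` the packaged Desikan-Killiany table (68 regions) is
    used.  Regions are re-ordered to the canonical order: left hemisphere
    first, then right, each alphabetical by name.

    Raises
    ------
    ValidationError
        On duplicate region names within a hemisphere or unknown hemisphere
        codes.
    """
    if path is None:
        ref = resources.files("covnet.data").joinpath(_DEFAULT_TABLE)
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", dtype=str)
    else:
        table = pd.read_csv(path, sep="\t", dtype=str)

    required = {"name", "hemisphere"}
    if not required.issubset(table.columns):
        raise ValidationError(
            f"region table must have columns {sorted(required)}, got {list(table.columns)}"
        )
    hemis = []
    for h in table["hemisphere"].str.strip().str.lower():
        if h not in _HEMI_CODES:
            raise ValidationError(f"unknown hemisphere code: {h!r}")
        hemis.append(_HEMI_CODES[h])
    names = table["name"].str.strip().tolist()
    rows = sorted(zip(names, hemis), key=lambda r: (0 if r[1] == "lh" else 1, r[0]))
    return RegionSet(
        names=tuple(r[0] for r in rows), hemispheres=tuple(r[1] for r in rows)
    )


def default_regions() -> RegionSet:
    """The packaged 68-region Desikan-Killiany set."""
    return load_region_table(None)
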