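"""Loaders for the packaged default resources.

The CGHR-10 category list (19 adult / 10 child / 7 neonatal causes), the
ICD-10 / WHO-VA-2016 code-range map, the CMEA-10 agreement groups, and the
synthetic probbases are shipped as editable CSV files under
``vaeval/data``.  The code lists are a reconstruction from published
cause names; users with authoritative tables should point the loaders at
their own files — every loader takes an optional path.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources as _ilr
from typing import Optional

from .codes import AgeStratum, CghrCategory, CmeaGroupTable, CodeMapTable

__all__ = [
    "default_categories",
    "default_code_map",
    "default_cmea_table",
    "default_probbase",
    "resource_path",
]


def resource_path(name: str):
    """Filesystem path of a packaged resource file."""
    return _ilr.files("vaeval.data").joinpath(name)


def load_categories(path) -> dict[AgeStratum, list[CghrCategory]]:
    """Read a category list from CSV with header ``stratum,id,label``."""
    out: dict[AgeStratum, list[CghrCategory]] = {s: [] for s in AgeStratum}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            s = AgeStratum(row["stratum"].strip())
            out[s].append(
                CghrCategory(id=row["id"].strip(), label=row["label"].strip(), age_stratum=s)
            )
    return out


@lru_cache(maxsize=1)
def default_categories() -> dict[AgeStratum, list[CghrCategory]]:
    return load_categories(resource_path("cghr10_categories.csv"))


@lru_cache(maxsize=1)
def default_code_map() -> CodeMapTable:
    return CodeMapTable.from_csv(resource_path("cghr10_map.csv"), default_categories())


@lru_cache(maxsize=1)
def default_cmea_table() -> CmeaGroupTable:
    return CmeaGroupTable.from_csv(resource_path("cmea10_groups.csv"))


def default_probbase(stratum: AgeStratum | str, path: Optional[str] = None):
    """The packaged synthetic probbase for one stratum.

    These are generated tables (see :func:`vaeval.synthetic.make_synthetic_probbase`)
    with no claim of fidelity to any published expert probbase.
    """
    from .coders import Probbase  # local import to avoid a cycle

    stratum = AgeStratum(stratum)
    src = path or resource_path(f"probbase_{stratum.value}.csv")
    return Probbase.from_csv(src)
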