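"""The 96-region brain parcellation shared by every table and graph.

The default atlas combines 80 bilateral cortical labels (AAL naming) with
16 subcortical labels (PD25 naming: caudate, putamen, external/internal
globus pallidus, thalamus, subthalamic nucleus, substantia nigra and red
nucleus, left/right).  Region order is fixed; every radiomic table and
metabolic graph in a run must share it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

N_REGIONS = 96
N_CORTICAL = 80
N_SUBCORTICAL = 16


@dataclass(frozen=True)
class Region:
    index: int  # 1-based
    name: str
    system: str  # "cortical" | "subcortical"


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered list of 96 regions of interest."""

    regions: tuple[Region, ...]

    def __post_init__(self):
        if len(self.regions) != N_REGIONS:
            raise ValueError(
                f"atlas must have {N_REGIONS} regions, got {len(self.regions)}")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("atlas region names must be unique")
        n_cort = sum(r.system == "cortical" for r in self.regions)
        n_sub = sum(r.system == "subcortical" for r in self.regions)
        if (n_cort, n_sub) != (N_CORTICAL, N_SUBCORTICAL):
            raise ValueError(
                f"expected {N_CORTICAL} cortical + {N_SUBCORTICAL} subcortical "
                f"regions, got {n_cort} + {n_sub}")
        for i, r in enumerate(self.regions, start=1):
            if r.index != i:
                raise ValueError(f"region indices must be 1..96 in order, "
                                 f"found {r.index} at position {i}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def index_of(self, name: str) -> int:
        """0-based position of a region name."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"region {name!r} not in atlas") from None

    def indices_of(self, names) -> list[int]:
        return [self.index_of(n) for n in names]


def load_atlas(path: str | Path | None = None) -> ROIAtlas:
    """Load an atlas TSV (columns: index, name, system).

    With no argument, returns the bundled 96-region AAL+PD25 atlas.
    """
    if path is None:
        ref = resources.files("r2snet.data").joinpath("atlas96.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = {"index", "name", "system"} - set(df.columns)
    if missing:
        raise ValueError(f"atlas file missing columns: {sorted(missing)}")
    regions = tuple(
        Region(int(r["index"]), str(r["name"]), str(r["system"]))
        for _, r in df.iterrows()
    )
    return ROIAtlas(regions)
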