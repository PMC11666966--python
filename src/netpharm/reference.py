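"""Loaders for the packaged reference tables.

These small text files transcribe published worked-example data for the
screening procedure: the 24-compound ADME-screened panel of *Hemerocallis
citrina* edible flower, the four published top-10 PPI hub lists (degree,
closeness, MNC, MCC), and the published per-target best docking energies.
They serve as ground-truth inputs for fixture-reproduction tests and demos;
nothing in the pipeline depends on them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import formats_io as fio
from .cdtd_network import DockingMatrix
from .compound_screen import CompoundRecord
from .target_assembly import TargetSet

__all__ = [
    "data_path",
    "load_compound_panel",
    "load_hub_top10",
    "load_docking_energies",
    "HUB_METRIC_FILES",
]

HUB_METRIC_FILES = {
    "dc": "hub_top10_degree.txt",
    "cc": "hub_top10_closeness.txt",
    "mnc": "hub_top10_mnc.txt",
    "mcc": "hub_top10_mcc.txt",
}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("netpharm") / "data" / name)


def load_compound_panel() -> list[CompoundRecord]:
    """The published 24-compound screened panel (with OB, DL, target counts)."""
    return fio.read_compound_table(data_path("hef_compounds.tsv"))


def load_hub_top10(metric: str) -> TargetSet:
    """One published top-10 hub list; ``metric`` in {dc, cc, mnc, mcc}.

    Order in the file reflects the published ranking; the return value is a
    set because only membership enters the central-target intersection.
    """
    return fio.read_gene_list(data_path(HUB_METRIC_FILES[metric]), label=metric)


def load_docking_energies() -> DockingMatrix:
    """The published per-target best binding energies (kcal/mol)."""
    return fio.read_docking_table(data_path("docking_best_energies.tsv"))
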