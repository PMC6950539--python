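"""Metabolite panel, multiplet templates and metabolic-network fixtures.

The quantified panel covers 27 small metabolites visible in 1D CPMG HRMAS
spectra of intestinal and hepatic tissue.  Each panel entry carries an
isolated quantification window (ppm interval) and the number of protons
resonating inside it; each metabolite additionally has a simplified multiplet
template (<= 2 Lorentzian components) used by the synthetic-spectrum
generator.  A hand-curated pathway-adjacency network over the same 27 names
(glycolysis, TCA cycle, choline/ethanolamine head-group metabolism,
amino-acid interconversions) supports the network-constrained
direction-of-change analysis.

All three fixtures ship as editable text files under ``netmet/data``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "MetabolitePanel",
    "MultipletTemplate",
    "MetabolicNetwork",
    "default_panel",
    "default_templates",
    "default_network",
    "load_network",
    "PANEL_SIZE",
]

PANEL_SIZE = 27

# chemical shifts must stay on the simulated axis
PPM_MIN, PPM_MAX = 0.70, 8.65


def _data_path(name: str):
    return resources.files("netmet.data").joinpath(name)


@dataclass(frozen=True)
class MultipletTemplate:
    """Simplified multiplet: a few Lorentzian components of unit total area.

    peaks: list of (center_ppm, relative_area, linewidth_fwhm_ppm)
    """

    metabolite: str
    peaks: tuple[tuple[float, float, float], ...]
    protons_per_molecule: int

    def __post_init__(self):
        total = sum(a for _, a, _ in self.peaks)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.metabolite}: relative areas sum to {total}, expected 1"
            )
        for c, _, _ in self.peaks:
            if not (PPM_MIN <= c <= PPM_MAX):
                raise ValueError(
                    f"{self.metabolite}: peak center {c} ppm outside "
                    f"[{PPM_MIN}, {PPM_MAX}]"
                )


@dataclass(frozen=True)
class MetabolitePanel:
    """Quantification panel: (name, window, protons) plus baseline levels."""

    entries: pd.DataFrame  # index: name; cols window_lo_ppm, window_hi_ppm, protons_in_window, baseline_nmol_per_mg

    def __post_init__(self):
        if self.entries.index.duplicated().any():
            raise ValueError("duplicate metabolite names in panel")
        bad = self.entries[
            self.entries.window_lo_ppm >= self.entries.window_hi_ppm
        ]
        if len(bad):
            raise ValueError(f"degenerate windows for {list(bad.index)}")

    @property
    def names(self) -> list[str]:
        return list(self.entries.index)

    def window(self, name: str) -> tuple[float, float]:
        row = self.entries.loc[name]
        return float(row.window_lo_ppm), float(row.window_hi_ppm)

    def protons(self, name: str) -> int:
        return int(self.entries.loc[name, "protons_in_window"])

    def baselines(self) -> pd.Series:
        return self.entries["baseline_nmol_per_mg"].astype(float)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path) -> "MetabolitePanel":
        df = pd.read_csv(path).set_index("name")
        return cls(df)


def default_panel() -> MetabolitePanel:
    """The 27-metabolite tissue panel with isolated quantification windows."""
    panel = MetabolitePanel.from_csv(_data_path("panel.csv"))
    assert len(panel) == PANEL_SIZE
    return panel


def default_templates() -> dict[str, MultipletTemplate]:
    """Lorentzian multiplet templates for every panel metabolite.

    Centers follow standard chemical-shift tables (e.g. the lactate doublet
    at 1.33 ppm), lightly adjusted so that quantification windows stay
    mutually isolated; only the quantified multiplet of each metabolite is
    modelled.
    """
    df = pd.read_csv(_data_path("multiplets.csv"))
    out: dict[str, MultipletTemplate] = {}
    for name, grp in df.groupby("metabolite", sort=False):
        out[name] = MultipletTemplate(
            metabolite=name,
            peaks=tuple(
                (float(r.center_ppm), float(r.rel_area), float(r.linewidth_ppm))
                for r in grp.itertuples()
            ),
            protons_per_molecule=int(grp.protons_per_molecule.iloc[0]),
        )
    return out


@dataclass
class MetabolicNetwork:
    """Undirected metabolite adjacency restricted to the panel."""

    graph: nx.Graph
    source: str = "curated pathway-adjacency fixture"

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def neighbors(self, name: str) -> list[str]:
        return sorted(self.graph.neighbors(name))


def load_network(edges, panel_names: list[str] | None = None,
                 source: str = "user edge list") -> MetabolicNetwork:
    """Build a validated network from an edge list (path or iterable of pairs).

    Every panel metabolite becomes a node; edges naming metabolites outside
    the panel raise; duplicate edges collapse; isolated panel nodes are kept
    with a warning.
    """
    if panel_names is None:
        panel_names = default_panel().names
    if isinstance(edges, (str, Path)) or hasattr(edges, "read_text"):
        text = Path(edges).read_text() if isinstance(edges, (str, Path)) else edges.read_text()
        pairs = [tuple(line.split("\t")) for line in text.splitlines() if line.strip()]
    else:
        pairs = [tuple(e) for e in edges]
    known = set(panel_names)
    offenders = sorted({n for e in pairs for n in e if n not in known})
    if offenders:
        raise ValueError(f"edge list names unknown metabolites: {offenders}")
    g = nx.Graph()
    g.add_nodes_from(panel_names)
    g.add_edges_from((a, b) for a, b in pairs if a != b)
    isolated = [n for n in panel_names if g.degree(n) == 0]
    if isolated:
        warnings.warn(
            f"{len(isolated)} panel metabolites are isolated in the network: "
            f"{isolated}", stacklevel=2,
        )
    return MetabolicNetwork(graph=g, source=source)


def default_network() -> MetabolicNetwork:
    """Curated pathway adjacency connecting all 27 panel metabolites."""
    return load_network(_data_path("network_edges.tsv"),
                        source="curated pathway-adjacency fixture")


def default_effect_table() -> pd.DataFrame:
    """Signed per-contrast concentration effects (log-SD units) used as the
    synthetic generator's defaults.

    Clinical-contrast columns encode the direction-of-change fixture at
    magnitude 1.0; tissue-contrast columns encode the discriminant-metabolite
    lists at magnitude 1.5.
    """
    return pd.read_csv(_data_path("effects.csv")).set_index("metabolite")
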