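"""Synthetic county geography: tracts, zips, health reporting areas (HRAs).

The statistical machinery downstream only sees three things: a tract
adjacency graph, a zip->tract crosswalk of residential-address ratios, and a
zip->HRA population-share table.  Real tract shapes are irrelevant, so the
generator lays tracts out on a rectangular grid (shared-edge adjacency) and
carves zips and HRAs out of contiguous runs of tracts.  Crosswalk ratios are
Dirichlet draws within each zip, mimicking the uneven split of residential
addresses across the tracts of a zip code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import rng_from_seed

__all__ = ["GeographyModel", "generate_geography"]

_NORM_TOL = 1e-9


@dataclass
class GeographyModel:
    """A county of tracts nested in zips, with tracts grouped into HRAs.

    Attributes
    ----------
    tract_ids, zip_ids, hra_ids : list of str
        Area identifiers.
    edges : list of (str, str)
        Symmetric, irreflexive tract adjacency (each undirected edge once).
    crosswalk : DataFrame with columns (zip, tract, res_ratio)
        Residential-address share of each tract within its zip; ratios sum
        to 1 within each zip.
    hra_share : DataFrame with columns (zip, hra, pop_share)
        Adult-population share of each HRA within a zip; sums to 1 per zip.
    tract_to_hra : dict
        Each tract belongs to exactly one HRA.
    """

    tract_ids: list[str]
    zip_ids: list[str]
    hra_ids: list[str]
    edges: list[tuple[str, str]]
    crosswalk: pd.DataFrame
    hra_share: pd.DataFrame
    tract_to_hra: dict[str, str]
    grid_shape: tuple[int, int] | None = None
    _tract_graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- views -------------------------------------------------------------

    def tract_graph(self) -> nx.Graph:
        if self._tract_graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.tract_ids)
            g.add_edges_from(self.edges)
            self._tract_graph = g
        return self._tract_graph

    def hra_graph(self) -> nx.Graph:
        """HRA adjacency induced by tract adjacency."""
        g = nx.Graph()
        g.add_nodes_from(self.hra_ids)
        for a, b in self.edges:
            ha, hb = self.tract_to_hra[a], self.tract_to_hra[b]
            if ha != hb:
                g.add_edge(ha, hb)
        return g

    def tract_to_zip(self) -> dict[str, str]:
        return dict(zip(self.crosswalk["tract"], self.crosswalk["zip"]))

    def zip_ratios(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per zip: (tract id array, res_ratio array)."""
        out = {}
        for z, grp in self.crosswalk.groupby("zip", sort=False):
            out[z] = (grp["tract"].to_numpy(), grp["res_ratio"].to_numpy(float))
        return out

    def tract_population(self) -> pd.Series:
        """Relative adult population per tract.

        Zips carry equal population; a tract's share is its residential
        ratio within its zip.  Normalised to sum to 1.
        """
        pop = self.crosswalk.set_index("tract")["res_ratio"] / len(self.zip_ids)
        return pop.reindex(self.tract_ids).rename("population")

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        cw = self.crosswalk
        sums = cw.groupby("zip")["res_ratio"].sum()
        if not np.allclose(sums, 1.0, atol=_NORM_TOL, rtol=0):
            bad = sums[~np.isclose(sums, 1.0, atol=_NORM_TOL, rtol=0)]
            raise ValueError(f"crosswalk res_ratio does not sum to 1 in zips: {list(bad.index)}")
        hs = self.hra_share.groupby("zip")["pop_share"].sum()
        if not np.allclose(hs, 1.0, atol=_NORM_TOL, rtol=0):
            bad = hs[~np.isclose(hs, 1.0, atol=_NORM_TOL, rtol=0)]
            raise ValueError(f"hra_share pop_share does not sum to 1 in zips: {list(bad.index)}")
        tracts = set(self.tract_ids)
        if set(cw["tract"]) != tracts:
            raise ValueError("every tract must appear in at least one crosswalk row")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"adjacency must be irreflexive (self-edge at {a})")
            if a not in tracts or b not in tracts:
                raise ValueError(f"edge ({a}, {b}) references unknown tract")
        g = self.tract_graph()
        if len(self.tract_ids) > 1 and not nx.is_connected(g):
            raise ValueError("tract adjacency graph is not connected")
        if set(self.tract_to_hra) != tracts:
            raise ValueError("tract_to_hra must cover every tract exactly once")

    # -- plain-text I/O ----------------------------------------------------

    def write(self, out_dir) -> None:
        """Write crosswalk, hra_share and adjacency as delimited tables."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.crosswalk.to_csv(out / "crosswalk.csv", index=False)
        self.hra_share.to_csv(out / "hra_share.csv", index=False)
        pd.DataFrame(self.edges, columns=["tract_a", "tract_b"]).to_csv(
            out / "adjacency.csv", index=False
        )
        pd.DataFrame(
            {"tract": list(self.tract_to_hra), "hra": list(self.tract_to_hra.values())}
        ).to_csv(out / "tract_to_hra.csv", index=False)

    @classmethod
    def read(cls, in_dir) -> "GeographyModel":
        from pathlib import Path

        p = Path(in_dir)
        crosswalk = pd.read_csv(p / "crosswalk.csv", dtype={"zip": str, "tract": str})
        hra_share = pd.read_csv(p / "hra_share.csv", dtype={"zip": str, "hra": str})
        adj = pd.read_csv(p / "adjacency.csv", dtype=str)
        t2h = pd.read_csv(p / "tract_to_hra.csv", dtype=str)
        return cls(
            tract_ids=sorted(crosswalk["tract"].unique()),
            zip_ids=sorted(crosswalk["zip"].unique()),
            hra_ids=sorted(hra_share["hra"].unique()),
            edges=list(adj.itertuples(index=False, name=None)),
            crosswalk=crosswalk,
            hra_share=hra_share,
            tract_to_hra=dict(zip(t2h["tract"], t2h["hra"])),
        )


def _contiguous_blocks(n_items: int, n_blocks: int) -> np.ndarray:
    """Balanced partition of range(n_items) into consecutive blocks."""
    return (np.arange(n_items) * n_blocks) // n_items


def generate_geography(
    n_tracts: int, n_zips: int, n_hras: int, seed: int | np.random.Generator,
    dirichlet_alpha: float = 2.0,
) -> GeographyModel:
    """Generate a grid county.

    Tracts are cells of a near-square rectangular grid with shared-edge
    adjacency.  Consecutive runs of tracts (row-major order) form zips and,
    independently, HRAs, so a zip can straddle an HRA boundary — which is
    what makes the zip->HRA population-share assignment non-trivial.
    Residential-address ratios within each zip are Dirichlet(alpha) draws.
    """
    if n_zips < 1 or n_tracts < n_zips:
        raise ValueError(f"need n_tracts >= n_zips >= 1; got n_tracts={n_tracts}, n_zips={n_zips}")
    if n_hras < 1 or n_tracts < n_hras:
        raise ValueError(f"need n_tracts >= n_hras >= 1; got n_tracts={n_tracts}, n_hras={n_hras}")
    rng = rng_from_seed(seed)

    width = len(str(n_tracts))
    tract_ids = [f"t{i:0{width}d}" for i in range(n_tracts)]
    zip_ids = [f"z{i:02d}" for i in range(n_zips)]
    hra_ids = [f"h{i:02d}" for i in range(n_hras)]

    ncol = int(np.ceil(np.sqrt(n_tracts)))
    edges: list[tuple[str, str]] = []
    for i in range(n_tracts):
        r, c = divmod(i, ncol)
        if c + 1 < ncol and i + 1 < n_tracts:
            edges.append((tract_ids[i], tract_ids[i + 1]))
        if i + ncol < n_tracts:
            edges.append((tract_ids[i], tract_ids[i + ncol]))
    # a partial last row can leave its tail cell without a right neighbour
    # below the grid body; row-major blocks keep the graph connected anyway,
    # but guard the degenerate 1-column case explicitly
    nrow = int(np.ceil(n_tracts / ncol))

    zip_of = _contiguous_blocks(n_tracts, n_zips)
    hra_of = _contiguous_blocks(n_tracts, n_hras)
    tract_to_hra = {tract_ids[i]: hra_ids[hra_of[i]] for i in range(n_tracts)}

    rows = []
    for zi in range(n_zips):
        members = np.flatnonzero(zip_of == zi)
        ratios = rng.dirichlet(np.full(members.size, dirichlet_alpha))
        ratios = ratios / ratios.sum()  # exact renormalisation
        for t, r in zip(members, ratios):
            rows.append((zip_ids[zi], tract_ids[t], r))
    crosswalk = pd.DataFrame(rows, columns=["zip", "tract", "res_ratio"])

    hs = (
        crosswalk.assign(hra=crosswalk["tract"].map(tract_to_hra))
        .groupby(["zip", "hra"], sort=True)["res_ratio"]
        .sum()
        .reset_index()
        .rename(columns={"res_ratio": "pop_share"})
    )
    # renormalise exactly per zip
    hs["pop_share"] = hs["pop_share"] / hs.groupby("zip")["pop_share"].transform("sum")
    return GeographyModel(
        tract_ids=tract_ids,
        zip_ids=zip_ids,
        hra_ids=hra_ids,
        edges=edges,
        crosswalk=crosswalk,
        hra_share=hs,
        tract_to_hra=tract_to_hra,
        grid_shape=(nrow, ncol),
    )
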