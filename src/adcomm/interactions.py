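"""Three-stage inference of species interactions and the import-flux niche map.

Stage 1 screens all species pairs by Pearson correlation of relative
abundance across samples (keep |r| >= 0.65 with p < 0.001).  Stage 2 turns
negative pairs into *competition* edges when both species import the same
compound above 0.01 mmol gDW^-1 h^-1 in at least one sample (shared
resource preference).  Stage 3 turns positive pairs into *mutualism* edges
when a compound exported by one above the threshold is imported by the
other above the threshold (metabolic products of one serving as substrates
for the other).  A correlated pair with no flux evidence stays a
co-occurrence only, so the edge count can be smaller than the screened
pair count.

Ecological niches are visualized by embedding each species' per-sample
import-flux vector into two dimensions with t-SNE; species consuming the
same compounds land close together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .fba import ExchangeMatrix
from .model import AnalysisConfig

__all__ = [
    "InteractionEdge",
    "NicheMap",
    "correlate_abundances",
    "screen_pairs",
    "infer_competition",
    "infer_mutualism",
    "embed_niches",
    "write_network",
    "read_network",
]


@dataclass
class InteractionEdge:
    species_a: str
    species_b: str
    type: str  # "mutualism" | "competition"
    r: float
    p: float
    #: (compound, flux_a, flux_b, direction); direction is "a->b"/"b->a" for
    #: mutualism (exporter first) and "shared" for competition
    compounds: list[tuple[str, float, float, str]] = field(default_factory=list)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.species_a, self.species_b))


@dataclass
class NicheMap:
    coordinates: dict[tuple[str, str], tuple[float, float]]  # (species, sample) -> xy
    cluster_labels: dict[tuple[str, str], int] | None = None


def correlate_abundances(abundances: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over samples (rows).

    Species with zero variance are excluded with a warning; fewer than three
    samples is an error.  p-values use the exact t transform with n-2
    degrees of freedom.
    """
    n = len(abundances)
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n}")
    variances = abundances.var(axis=0, ddof=0)
    keep = variances[variances > 0].index
    dropped = sorted(set(abundances.columns) - set(keep))
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "excluding zero-variance species from correlation: %s", dropped)
    r = abundances[keep].corr(method="pearson")
    rv = r.to_numpy(copy=True)
    np.clip(rv, -1.0, 1.0, out=rv)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    return r, p


def screen_pairs(r: pd.DataFrame, p: pd.DataFrame,
                 config: AnalysisConfig | None = None
                 ) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Partition pairs passing |r| >= threshold and p < threshold by sign."""
    config = config or AnalysisConfig()
    if config.use_fdr:
        from statsmodels.stats.multitest import multipletests

        pairs = list(combinations(r.columns, 2))
        raw = np.array([p.loc[a, b] for a, b in pairs])
        adj = multipletests(raw, method="fdr_bh")[1]
        p = p.copy()
        for (a, b), q in zip(pairs, adj):
            p.loc[a, b] = p.loc[b, a] = q
    positive, negative = [], []
    for a, b in combinations(sorted(r.columns), 2):
        rv, pv = r.loc[a, b], p.loc[a, b]
        if abs(rv) >= config.corr_r_threshold and pv < config.corr_p_threshold:
            (positive if rv > 0 else negative).append((a, b))
    return positive, negative


def _flux_evidence(pairs, exchanges, config, kind):
    """Per-pair compound evidence across samples under the threshold rule."""
    thr = config.flux_threshold
    skip = set(config.currency_compounds)
    out: dict[tuple[str, str], dict[tuple, int]] = {}
    for ex in exchanges.values() if isinstance(exchanges, dict) else exchanges:
        for a, b in pairs:
            compounds = out.setdefault((a, b), {})
            if kind == "competition":
                for cpd in {c for (s, c) in ex.imports if s in (a, b) and c not in skip}:
                    ia = ex.imports.get((a, cpd), 0.0)
                    ib = ex.imports.get((b, cpd), 0.0)
                    if ia > thr and ib > thr:
                        key = (cpd, "shared")
                        compounds[key] = compounds.get(key, 0) + 1
                        rec = compounds.setdefault((cpd, "shared", "flux"), [0.0, 0.0])
                        rec[0] = max(rec[0], ia)
                        rec[1] = max(rec[1], ib)
            else:
                for exporter, importer, tag in ((a, b, "a->b"), (b, a, "b->a")):
                    for cpd in {c for (s, c) in ex.exports if s == exporter and c not in skip}:
                        ev = ex.exports.get((exporter, cpd), 0.0)
                        iv = ex.imports.get((importer, cpd), 0.0)
                        if ev > thr and iv > thr:
                            key = (cpd, tag)
                            compounds[key] = compounds.get(key, 0) + 1
                            rec = compounds.setdefault((cpd, tag, "flux"), [0.0, 0.0])
                            rec[0] = max(rec[0], ev)
                            rec[1] = max(rec[1], iv)
    return out


def infer_competition(negative_pairs: list[tuple[str, str]],
                      exchanges: dict[str, ExchangeMatrix],
                      r: pd.DataFrame, p: pd.DataFrame,
                      config: AnalysisConfig | None = None) -> list[InteractionEdge]:
    """Competition edges: negatively correlated pairs sharing an imported
    compound above the flux threshold in >= ``config.min_samples`` samples."""
    config = config or AnalysisConfig()
    evidence = _flux_evidence(negative_pairs, exchanges, config, "competition")
    edges = []
    for a, b in negative_pairs:
        compounds = []
        for key, count in evidence.get((a, b), {}).items():
            if len(key) != 2:
                continue
            cpd, tag = key
            if count >= config.min_samples:
                fa, fb = evidence[(a, b)][(cpd, tag, "flux")]
                compounds.append((cpd, fa, fb, "shared"))
        if compounds:
            edges.append(InteractionEdge(a, b, "competition",
                                         float(r.loc[a, b]), float(p.loc[a, b]),
                                         sorted(compounds)))
    return edges


def infer_mutualism(positive_pairs: list[tuple[str, str]],
                    exchanges: dict[str, ExchangeMatrix],
                    r: pd.DataFrame, p: pd.DataFrame,
                    config: AnalysisConfig | None = None) -> list[InteractionEdge]:
    """Mutualism edges: positively correlated pairs where one's export is the
    other's import, both above the flux threshold, in >= ``min_samples``
    samples (either direction)."""
    config = config or AnalysisConfig()
    evidence = _flux_evidence(positive_pairs, exchanges, config, "mutualism")
    edges = []
    for a, b in positive_pairs:
        compounds = []
        for key, count in evidence.get((a, b), {}).items():
            if len(key) != 2:
                continue
            cpd, tag = key
            if count >= config.min_samples:
                fe, fi = evidence[(a, b)][(cpd, tag, "flux")]
                compounds.append((cpd, fe, fi, tag))
        if compounds:
            edges.append(InteractionEdge(a, b, "mutualism",
                                         float(r.loc[a, b]), float(p.loc[a, b]),
                                         sorted(compounds)))
    return edges


def embed_niches(exchanges: dict[str, ExchangeMatrix],
                 config: AnalysisConfig | None = None,
                 cluster: bool = False) -> NicheMap:
    """t-SNE embedding of (species, sample) import-flux vectors.

    Deterministic for a fixed ``config.rng_seed``.  Optional DBSCAN cluster
    labels are advisory (niche groups were delineated manually in the study
    this emulates).
    """
    config = config or AnalysisConfig()
    rows = {}
    compounds = sorted({c for ex in exchanges.values() for (_, c) in ex.imports})
    for sample_id in sorted(exchanges):
        ex = exchanges[sample_id]
        for sid in sorted({s for (s, _) in ex.imports}):
            rows[(sid, sample_id)] = [ex.imports.get((sid, c), 0.0) for c in compounds]
    if not rows:
        raise ValueError("no import fluxes to embed")
    X = np.asarray(list(rows.values()))
    n = len(rows)
    perplexity = min(config.tsne_perplexity, (n - 1) / 3.0)
    if perplexity < 1:
        raise ValueError(
            f"{n} points are too few for t-SNE; lower the perplexity or add samples")
    from sklearn.manifold import TSNE

    emb = TSNE(n_components=2, random_state=config.rng_seed,
               perplexity=perplexity, init="pca").fit_transform(X)
    coords = {key: (float(x), float(y)) for key, (x, y) in zip(rows, emb)}
    labels = None
    if cluster:
        from sklearn.cluster import DBSCAN

        lab = DBSCAN(eps=np.median(np.abs(emb)) / 2 + 1e-9, min_samples=5).fit_predict(emb)
        labels = {key: int(v) for key, v in zip(rows, lab)}
    return NicheMap(coordinates=coords, cluster_labels=labels)


def _edges_graph(edges: list[InteractionEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.species_a, e.species_b, type=e.type, r=e.r, p=e.p,
                   compounds=";".join(f"{c}({d})" for c, _, _, d in e.compounds))
    return g


def write_network(edges: list[InteractionEdge], path, format: str = "graphml") -> None:
    if format == "graphml":
        nx.write_graphml(_edges_graph(edges), path)
    elif format == "edge-tsv":
        pd.DataFrame([
            {"species_a": e.species_a, "species_b": e.species_b, "type": e.type,
             "r": e.r, "p": e.p,
             "compounds": ";".join(f"{c}({d})" for c, _, _, d in e.compounds)}
            for e in edges
        ], columns=["species_a", "species_b", "type", "r", "p", "compounds"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> list[InteractionEdge]:
    if format == "graphml":
        g = nx.read_graphml(path)
        return sorted(
            (InteractionEdge(a, b, d["type"], float(d["r"]), float(d["p"]))
             for a, b, d in g.edges(data=True)),
            key=lambda e: (e.species_a, e.species_b))
    if format == "edge-tsv":
        df = pd.read_csv(path, sep="\t")
        return [InteractionEdge(row.species_a, row.species_b, row.type,
                                float(row.r), float(row.p))
                for row in df.itertuples(index=False)]
    raise ValueError(f"unknown network format {format!r}")
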