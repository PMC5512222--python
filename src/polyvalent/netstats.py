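"""Network-parameter battery for domain networks.

Covers the statistics used to characterize the domain network of polyvalent
proteins: the degree distribution and its discrete power-law fit
(maximum-likelihood exponent with KS-minimizing lower cutoff and a
semi-parametric bootstrap p value), shortest-path betweenness, HITS
hub/authority scores, maximal cliques and the subnetwork merging the
largest of them, the largest biconnected subnetwork, and the exponential
fit to the domains-per-protein histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
from scipy import optimize, special, stats

from ._errors import ConvergenceError, DegenerateError, SizeError, UsageError
from .networks import DomainNetwork

__all__ = [
    "PowerLawFit", "ExponentialFit", "NetworkStatsReport",
    "degree_sequence", "fit_power_law", "fit_exponential_decay",
    "betweenness", "hits_scores", "maximal_cliques",
    "merge_largest_cliques", "largest_biconnected",
    "compute_network_report", "sample_discrete_power_law",
]


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    ks_stat: float
    p_value: float | None
    n_tail: int


@dataclass
class ExponentialFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass
class NetworkStatsReport:
    degree: dict
    betweenness: dict
    hub_score: dict | None
    authority_score: dict | None
    cliques: list
    clique_subnetwork: dict
    largest_biconnected: dict
    power_law: PowerLawFit | None
    notes: str = ""

    def to_jsonable(self) -> dict:
        d = {
            "degree": self.degree,
            "betweenness": self.betweenness,
            "hub_score": self.hub_score,
            "authority_score": self.authority_score,
            "cliques": [sorted(c) for c in self.cliques],
            "clique_subnetwork": self.clique_subnetwork,
            "largest_biconnected": self.largest_biconnected,
            "power_law": asdict(self.power_law) if self.power_law else None,
            "notes": self.notes,
        }
        return d


# ---------------------------------------------------------------------------
# degrees

def degree_sequence(net: DomainNetwork, mode: str = "total") -> list[int]:
    """Unweighted degrees, one per node, sorted descending.

    ``total`` counts distinct neighbors (undirected view for directed
    networks); ``in``/``out`` require a directed network.
    """
    if mode == "total":
        g = net.undirected_view() if net.directed else net.graph
        degs = [d for _, d in g.degree()]
    elif mode in ("in", "out"):
        if not net.directed:
            raise UsageError(f"mode={mode!r} requires a directed network")
        degview = net.graph.in_degree() if mode == "in" else net.graph.out_degree()
        degs = [d for _, d in degview]
    else:
        raise UsageError(f"unknown degree mode {mode!r}")
    return sorted(degs, reverse=True)


# ---------------------------------------------------------------------------
# discrete power-law fit (maximum likelihood, KS-minimizing xmin)

_MIN_VALUES = 10  # smallest sample admitted for fitting


def _alpha_mle(tail: np.ndarray, xmin: int) -> float:
    n = tail.size
    slogx = float(np.log(tail).sum())

    def nll(alpha: float) -> float:
        return n * math.log(special.zeta(alpha, xmin)) + alpha * slogx

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 10.0), method="bounded")
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.arange(xmin, tail.max() + 1)
    # fitted CDF on [xmin, x]: 1 - zeta(alpha, x+1)/zeta(alpha, xmin)
    z0 = special.zeta(alpha, xmin)
    fit_cdf = 1.0 - special.zeta(alpha, xs + 1) / z0
    emp_cdf = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
    return float(np.abs(emp_cdf - fit_cdf).max())


def _fit_tail(values: np.ndarray) -> tuple[float, int, float, int]:
    """Scan candidate xmins; return (alpha, xmin, ks, n_tail) at the KS minimum.

    Every unique value whose tail still holds two distinct values is a
    candidate (the plfit convention, as in igraph's fit).
    """
    best = None
    for xmin in np.unique(values):
        tail = values[values >= xmin]
        if np.unique(tail).size < 2:
            continue
        xmin = int(xmin)
        alpha = _alpha_mle(tail, xmin)
        ks = _ks_distance(tail, alpha, xmin)
        if best is None or ks < best[2]:
            best = (alpha, xmin, ks, tail.size)
    if best is None:  # single distinct value; caller guards, but stay safe
        raise DegenerateError("degenerate tail: all values equal")
    return best


_SAMPLER_CAP = 100_000  # exact inverse-CDF below; continuous tail above


def sample_discrete_power_law(
    n: int, alpha: float, xmin: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-transform sampler for the discrete power law.

    Exact tabulated CDF up to a large cap; the rare mass beyond the cap uses
    the rounded continuous approximation, which is accurate at large x.
    """
    xs = np.arange(xmin, xmin + _SAMPLER_CAP)
    z0 = special.zeta(alpha, xmin)
    cdf = 1.0 - special.zeta(alpha, xs + 1) / z0
    u = rng.random(n)
    out = xs[np.minimum(np.searchsorted(cdf, u, side="right"), _SAMPLER_CAP - 1)]
    over = u > cdf[-1]
    if over.any():
        out = out.copy()
        out[over] = np.floor(
            (xmin - 0.5) * (1.0 - u[over]) ** (-1.0 / (alpha - 1.0)) + 0.5
        ).astype(int)
    return out.astype(int)


def fit_power_law(
    degrees, n_bootstrap: int = 250, seed: int = 0
) -> PowerLawFit:
    """Discrete MLE power-law fit with KS-minimizing lower cutoff.

    The exponent is the discrete maximum-likelihood estimate for each
    candidate cutoff; the cutoff minimizing the KS distance between the
    empirical and fitted tail CDFs is kept.  The p value comes from a
    semi-parametric bootstrap: each replicate resamples the empirical body
    below the cutoff and draws the tail from the fitted model, is refitted
    from scratch, and p is the fraction of replicates whose KS distance is
    at least the observed one.  ``n_bootstrap=0`` skips the bootstrap
    (p_value is None).  Deterministic given ``seed``.
    """
    values = np.asarray([d for d in degrees if d > 0], dtype=float)
    if values.size < _MIN_VALUES:
        raise SizeError(f"need >= {_MIN_VALUES} positive values, got {values.size}")
    if np.unique(values).size == 1:
        raise DegenerateError("all degrees equal; power-law fit is degenerate")
    alpha, xmin, ks, n_tail = _fit_tail(values)
    p_value = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        body = values[values < xmin]
        n = values.size
        p_tail = n_tail / n
        exceed = 0
        for _ in range(n_bootstrap):
            from_tail = rng.random(n) < p_tail
            k_tail = int(from_tail.sum())
            parts = []
            if k_tail:
                parts.append(sample_discrete_power_law(k_tail, alpha, xmin, rng))
            if n - k_tail:
                if body.size:
                    parts.append(rng.choice(body, size=n - k_tail, replace=True))
                else:
                    parts.append(sample_discrete_power_law(n - k_tail, alpha, xmin, rng))
            synth = np.concatenate(parts).astype(float)
            if np.unique(synth).size == 1:
                continue
            _, _, ks_b, _ = _fit_tail(synth)
            if ks_b >= ks:
                exceed += 1
        p_value = exceed / n_bootstrap
    return PowerLawFit(alpha=alpha, xmin=int(xmin), ks_stat=ks, p_value=p_value,
                       n_tail=int(n_tail))


# ---------------------------------------------------------------------------
# exponential decay of the domains-per-protein histogram

def fit_exponential_decay(counts: dict, min_count: int = 1) -> ExponentialFit:
    """OLS of natural-log protein counts on domains-per-protein (bins >= 2).

    Bins below ``min_count`` are dropped rather than log-transformed.
    """
    pts = sorted((k, c) for k, c in counts.items() if k >= 2 and c >= min_count)
    if len(pts) < 3:
        raise SizeError(f"need >= 3 usable bins, got {len(pts)}")
    x = np.array([k for k, _ in pts], dtype=float)
    y = np.log([c for _, c in pts])
    if np.allclose(y, y[0]):  # flat histogram: zero slope, nothing explained
        return ExponentialFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                              p_value=1.0)
    res = stats.linregress(x, y)
    return ExponentialFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# centralities

def betweenness(net: DomainNetwork, normalized: bool = False) -> dict:
    """Shortest-path betweenness on the unweighted graph.

    Directed networks use directed paths; pair contributions are split
    equally among equal-length shortest paths.
    """
    return dict(nx.betweenness_centrality(net.graph, normalized=normalized))


def hits_scores(
    net: DomainNetwork, tol: float = 1e-10, max_iter: int = 1000, scale_max: bool = False
) -> tuple[dict, dict]:
    """HITS hub/authority scores by mutually reinforcing power iteration.

    Authorities accumulate the hub scores of their in-neighbors; hubs
    accumulate the authority scores of their out-neighbors; both vectors are
    L2-normalized each step from a uniform start, until the largest
    per-node change falls below ``tol``.  ``scale_max=True`` additionally
    rescales each vector so its maximum is 1 for readability.
    """
    if not net.directed:
        raise UsageError("HITS requires a directed network")
    g = net.graph
    if g.number_of_edges() == 0:
        raise DegenerateError("HITS is undefined on a network with no edges")
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, weight=None, format="csr")
    h = np.full(n, 1.0 / math.sqrt(n))
    auth = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        new_auth = a.T @ h
        na = np.linalg.norm(new_auth)
        new_auth = new_auth / na if na > 0 else new_auth
        new_h = a @ new_auth
        nh = np.linalg.norm(new_h)
        new_h = new_h / nh if nh > 0 else new_h
        resid = max(np.abs(new_h - h).max(), np.abs(new_auth - auth).max())
        h, auth = new_h, new_auth
        if resid < tol:
            break
    else:
        raise ConvergenceError(
            f"HITS did not converge in {max_iter} iterations", residual=float(resid)
        )
    if scale_max:
        h = h / h.max() if h.max() > 0 else h
        auth = auth / auth.max() if auth.max() > 0 else auth
    return ({nd: float(h[idx[nd]]) for nd in nodes},
            {nd: float(auth[idx[nd]]) for nd in nodes})


# ---------------------------------------------------------------------------
# cliques and biconnectivity (undirected views)

def maximal_cliques(net: DomainNetwork) -> list[list[str]]:
    """All maximal cliques, each sorted, list ordered by (size desc, lexicographic)."""
    g = net.undirected_view()
    cliques = [sorted(c) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def merge_largest_cliques(net: DomainNetwork, min_size: int) -> nx.Graph:
    """Induced subgraph on the union of all maximal cliques of size >= min_size."""
    if min_size < 2:
        raise UsageError("min_size must be >= 2")
    g = net.undirected_view()
    union: set[str] = set()
    for c in maximal_cliques(net):
        if len(c) >= min_size:
            union.update(c)
    return g.subgraph(union).copy()


def largest_biconnected(net: DomainNetwork) -> nx.Graph:
    """The biconnected component with the most nodes (induced subgraph).

    Single edges count as biconnected components of size 2; ties are broken
    by the lexicographically smallest sorted node set.  An empty graph
    yields an empty subgraph.
    """
    g = net.undirected_view()
    comps = [sorted(c) for c in nx.biconnected_components(g)]
    if not comps:
        return nx.Graph()
    comps.sort(key=lambda c: (-len(c), c))
    return g.subgraph(comps[0]).copy()


# ---------------------------------------------------------------------------
# report assembly

def _subgraph_dict(sg: nx.Graph) -> dict:
    return {
        "nodes": sorted(sg.nodes),
        "edges": sorted([sorted((u, v)) for u, v in sg.edges]),
    }


def compute_network_report(
    net: DomainNetwork,
    min_clique_size: int = 7,
    n_bootstrap: int = 250,
    seed: int = 0,
    adjacency_net: DomainNetwork | None = None,
) -> NetworkStatsReport:
    """The full battery on a (typically co-occurrence) network.

    Hub/authority scores need direction; they are computed on
    ``adjacency_net`` when given and skipped otherwise.
    """
    g = net.undirected_view() if net.directed else net.graph
    degree = {n: d for n, d in g.degree()}
    btw = betweenness(net, normalized=False)
    hub = auth = None
    if adjacency_net is not None:
        hub, auth = hits_scores(adjacency_net, scale_max=True)
    cliques = maximal_cliques(net)
    clique_sub = merge_largest_cliques(net, min_clique_size)
    bicomp = largest_biconnected(net)
    degs = degree_sequence(net, "total")
    try:
        pl = fit_power_law(degs, n_bootstrap=n_bootstrap, seed=seed)
    except (SizeError, DegenerateError):
        pl = None
    frac = len(bicomp) / g.number_of_nodes() if g.number_of_nodes() else 0.0
    return NetworkStatsReport(
        degree=degree,
        betweenness=btw,
        hub_score=hub,
        authority_score=auth,
        cliques=cliques,
        clique_subnetwork=_subgraph_dict(clique_sub),
        largest_biconnected=_subgraph_dict(bicomp),
        power_law=pl,
        notes=(
            f"largest biconnected subnetwork covers {len(bicomp)} nodes "
            f"({100 * frac:.1f}% of the network)"
        ),
    )
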