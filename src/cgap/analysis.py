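"""Statistics and derived quantities for binding-event campaigns.

Covers the exact multinomial/binomial significance test on event counts,
geometric censuses of P-site proximity to the catalytic site, the
relative-phosphorylation-rate prediction ``v_phos = k'_intra * (kcat/KM)``
combining simulated binding frequencies with peptide catalytic
efficiencies, the triangular-null audit of initial-structure correlation,
and campaign summaries.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .protocols import BindingEventTable, EventRecord

# ---------------------------------------------------------------------------
# Exact multinomial test
# ---------------------------------------------------------------------------

#: above this total count, >2-category tests switch to Monte Carlo
EXACT_ENUMERATION_LIMIT = 60


@dataclasses.dataclass
class MultinomialTestResult:
    p_value: float
    method: str  # 'binomial-exact' | 'multinomial-exact' | 'monte-carlo'
    standard_error: float = 0.0

    def __float__(self):
        return self.p_value


def cis_trans_test(counts: Sequence[int], seed: int = 0, n_draws: int = 100_000) -> MultinomialTestResult:
    """Exact test of the equiprobable multinomial null on event counts.

    Two categories use the exact two-sided binomial (two-sidedness by the
    minimum-likelihood convention: sum of outcome probabilities no larger
    than the observed one).  More categories use exact enumeration when the
    total is small, otherwise seeded Monte Carlo with the same likelihood
    ordering and a reported standard error.
    """
    counts = [int(c) for c in counts]
    if len(counts) < 2:
        raise ValueError("need at least two categories")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all-zero counts: test undefined")
    k = len(counts)
    if k == 2:
        p = stats.binomtest(counts[0], n, 0.5, alternative="two-sided").pvalue
        return MultinomialTestResult(float(p), "binomial-exact")
    probs = np.full(k, 1.0 / k)
    logp_obs = stats.multinomial.logpmf(counts, n, probs)
    if n <= EXACT_ENUMERATION_LIMIT:
        total = 0.0
        for combo in itertools.combinations(range(n + k - 1), k - 1):
            # stars-and-bars composition of n into k parts
            parts = []
            prev = -1
            for c in combo:
                parts.append(c - prev - 1)
                prev = c
            parts.append(n + k - 2 - prev)
            lp = stats.multinomial.logpmf(parts, n, probs)
            if lp <= logp_obs + 1e-12:
                total += math.exp(lp)
        return MultinomialTestResult(min(total, 1.0), "multinomial-exact")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_draws)
    lps = stats.multinomial.logpmf(draws, n, probs)
    hits = np.mean(lps <= logp_obs + 1e-12)
    se = math.sqrt(hits * (1 - hits) / n_draws)
    return MultinomialTestResult(float(hits), "monte-carlo", standard_error=se)


# ---------------------------------------------------------------------------
# Geometric censuses
# ---------------------------------------------------------------------------


def proximity_census(
    members: Sequence[np.ndarray],
    anchor_bead: int,
    site_beads: dict,
    radius: float = 40.0,
) -> pd.Series:
    """Count ensemble members with each P-site tyrosine within the radius.

    The ball is closed: a tyrosine at exactly the radius is included.
    ``site_beads`` maps site label -> tyrosine bead index.
    """
    counts = {site: 0 for site in site_beads}
    for coords in members:
        a = coords[anchor_bead]
        for site, bead in site_beads.items():
            if np.linalg.norm(coords[bead] - a) <= radius:
                counts[site] += 1
    return pd.Series(counts, dtype=int)


def distance_distributions(
    members: Sequence[np.ndarray],
    anchor_bead: int,
    site_beads: dict,
    bins=None,
    subset_radius: float = 30.0,
) -> dict:
    """Per-site anchor-distance samples, histograms and the <=radius subset.

    Returns ``{site: {"distances", "hist", "bin_edges", "subset_members"}}``;
    ``subset_members`` lists member indices whose tyrosine lies within the
    (closed) subset radius, for structure-gallery export.
    """
    out = {}
    for site, bead in site_beads.items():
        d = np.array([np.linalg.norm(c[bead] - c[anchor_bead]) for c in members])
        if bins is None:
            edges = np.histogram_bin_edges(d, bins=20) if len(d) else np.linspace(0, 1, 2)
        else:
            edges = np.asarray(bins, dtype=float)
        hist, edges = np.histogram(d, bins=edges)
        out[site] = {
            "distances": d,
            "hist": hist,
            "bin_edges": edges,
            "subset_members": np.flatnonzero(d <= subset_radius),
        }
    return out


# ---------------------------------------------------------------------------
# v_phos prediction
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PSiteKineticsTable:
    """Per-site peptide catalytic efficiencies kcat/KM (mM^-1 min^-1)."""

    table: pd.DataFrame  # index: site label (str); columns include kcat_km

    @classmethod
    def packaged(cls) -> "PSiteKineticsTable":
        """The shipped table of published peptide-substrate efficiencies."""
        ref = importlib.resources.files("cgap.data").joinpath("psite_kinetics.tsv")
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", dtype={"site": str})
        df = df.set_index("site")
        if (df["kcat_km_mM_min"].dropna() <= 0).any():
            raise ValueError("kcat/KM values must be positive")
        return cls(df)

    def kcat_km(self, site: str) -> float:
        try:
            v = self.table.loc[str(site), "kcat_km_mM_min"]
        except KeyError:
            return float("nan")
        return float(v) if pd.notna(v) else float("nan")


@dataclasses.dataclass
class VphosPrediction:
    """Relative self-phosphorylation velocities per site.

    ``k_intra`` is the relative catalytic-site binding frequency (cis+trans
    summed per site, normalized to sum 1); ``v_phos = k_intra * kcat/KM``.
    Sites lacking kinetics carry NaN.  Both quantities are relative: any
    uniform rescaling of the frequencies rescales v_phos uniformly.
    """

    frame: pd.DataFrame  # columns: count, k_intra, kcat_km, v_phos


def predict_vphos(
    site_counts: dict | pd.Series,
    kinetics: PSiteKineticsTable,
    require_charge_stripped: bool = True,
    charge_stripped: bool = True,
) -> VphosPrediction:
    """Combine binding frequencies with peptide kinetics into v_phos.

    ``site_counts`` are per-site event counts summed over receiver and
    activator copies, from a campaign without tail electrostatics (the
    frequencies then reflect topology alone); pass
    ``charge_stripped=False`` with ``require_charge_stripped=False`` to
    override deliberately.
    """
    if require_charge_stripped and not charge_stripped:
        raise ValueError("v_phos expects frequencies from a charge-stripped campaign")
    counts = pd.Series(site_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("no binding events to normalize")
    k_intra = counts / total
    kk = pd.Series({s: kinetics.kcat_km(s) for s in counts.index})
    frame = pd.DataFrame(
        {"count": counts, "k_intra": k_intra, "kcat_km": kk, "v_phos": k_intra * kk}
    )
    return VphosPrediction(frame)


# ---------------------------------------------------------------------------
# Initial-structure correlation audit
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CorrelationAudit:
    """Same-site event pairs' start-structure time gaps vs the triangular null.

    For two times drawn uniformly from [0, T] the density of their gap is
    p(dt) = (2/T)(1 - dt/T), i.e. linearly decreasing to zero at dt = T.
    Excess observed mass at small gaps flags start-structure correlation.
    """

    delta_t: np.ndarray
    total_time: float
    bin_edges: np.ndarray
    observed: np.ndarray
    expected: np.ndarray

    def excess_small_gap(self) -> float:
        """Observed-minus-expected count in the smallest-gap bin."""
        if not len(self.observed):
            return 0.0
        return float(self.observed[0] - self.expected[0])


def triangular_null_density(dt: np.ndarray, total_time: float) -> np.ndarray:
    dt = np.asarray(dt, dtype=float)
    return np.where((dt >= 0) & (dt <= total_time), 2.0 / total_time * (1.0 - dt / total_time), 0.0)


def correlation_audit(
    records: Sequence[EventRecord],
    ensemble,
    total_time_ns: float,
    n_bins: int = 10,
) -> CorrelationAudit:
    """Audit whether same-site events cluster by start-structure sample time.

    Only pairs of events that bound the same site *and* started from
    members of the same randomization trajectory are compared; their
    sample-time gaps are histogrammed against the triangular null scaled to
    the same number of pairs.
    """
    gaps = []
    eventful = [r for r in records if not r.timed_out and r.initial_structure >= 0]
    for a, b in itertools.combinations(eventful, 2):
        if a.site != b.site:
            continue
        ta = ensemble.trajectory_id[a.initial_structure]
        tb = ensemble.trajectory_id[b.initial_structure]
        if ta != tb:
            continue
        gaps.append(
            abs(
                ensemble.sample_time_ns[a.initial_structure]
                - ensemble.sample_time_ns[b.initial_structure]
            )
        )
    gaps = np.asarray(gaps)
    edges = np.linspace(0.0, total_time_ns, n_bins + 1)
    observed, _ = np.histogram(gaps, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = triangular_null_density(centers, total_time_ns)
    widths = np.diff(edges)
    expected = dens * widths * len(gaps)
    return CorrelationAudit(gaps, total_time_ns, edges, observed, expected)


# ---------------------------------------------------------------------------
# Campaign summary
# ---------------------------------------------------------------------------


def summarize_campaign(
    table: BindingEventTable,
    records: Sequence[EventRecord] | None = None,
    exclude_sites: Sequence[str] = (),
    seed: int = 0,
) -> dict:
    """Campaign report: totals, cis/trans split and its exact test.

    ``exclude_sites`` re-runs the cis/trans comparison with the named sites
    removed (site labels are matched with their chain suffix stripped, so
    excluding "992" drops both copies).
    """
    counts = table.counts
    cis = int(counts["cis"].sum())
    trans = int(counts["trans"].sum())
    report = {
        "n_trials": table.n_trials,
        "n_events": table.n_events,
        "n_timeouts": table.n_timeouts,
        "total_simulated_us": table.total_simulated_ns / 1000.0,
        "mean_event_time_us": table.mean_event_time_ns / 1000.0,
        "cis_events": cis,
        "trans_events": trans,
        "per_site": {str(s): int(v) for s, v in table.site_totals().items()},
    }
    if cis + trans > 0:
        report["cis_trans_p"] = cis_trans_test([cis, trans], seed=seed).p_value
    if exclude_sites:
        def base(site):
            return str(site).rstrip("AB")

        keep = [s for s in counts.index if base(s) not in {str(e) for e in exclude_sites}]
        sub = counts.loc[keep]
        c2, t2 = int(sub["cis"].sum()), int(sub["trans"].sum())
        report["excluded"] = {
            "sites": list(exclude_sites),
            "cis_events": c2,
            "trans_events": t2,
            "cis_trans_p": cis_trans_test([c2, t2], seed=seed).p_value if c2 + t2 else None,
        }
    return report
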