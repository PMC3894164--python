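"""Experiment designs: randomization ensembles and binding-event campaigns.

A campaign models one autophosphorylation binding event per trial: a start
structure is drawn at random from an ensemble of conformation-randomized
receptors, the dimer is propagated under Brownian dynamics, and the trial
ends when any P-site forms all of its trigger contacts with the catalytic
site simultaneously (or at the timeout).  Variants: the randomization runs
themselves (P-site attractions removed so no stable docking can occur),
charge-stripped tails (probing the role of tail electrostatics), and
second-event campaigns started from bound states with the first site's
phosphorylation mimicked.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .coarse_grain import CGSystem
from .dynamics import IntegratorConfig, RunResult, compile_system, run
from .forcefield import GoForceField


@dataclasses.dataclass
class EnsembleSettings:
    """Randomization-ensemble shape.

    The production design is five independent 10 us trajectories sampled
    every 0.1 us (500 members); tests and desk-scale campaigns scale all
    three numbers down.
    """

    n_trajectories: int = 5
    duration_ns: float = 10_000.0
    interval_ns: float = 100.0

    @property
    def members_per_trajectory(self) -> int:
        return int(round(self.duration_ns / self.interval_ns))


@dataclasses.dataclass
class EnsembleSet:
    """Conformation-randomized start structures with provenance."""

    members: list  # list of (N, 3) coordinate arrays
    trajectory_id: np.ndarray  # (M,)
    sample_time_ns: np.ndarray  # (M,)
    settings: EnsembleSettings
    psite_attractions_removed: bool = True

    def __len__(self) -> int:
        return len(self.members)


def randomize_ensemble(
    system: CGSystem,
    ff: GoForceField,
    config: IntegratorConfig,
    settings: EnsembleSettings,
    seed: int = 0,
) -> EnsembleSet:
    """Generate start structures by running with P-site attractions removed.

    Removing every attractive term tagged ``psite:*`` precludes stable
    P-site/active-site docking, so tail conformations randomize freely.
    Unstable trajectories are dropped with a warning.
    """
    stripped = system.strip_psite_attractions()
    members, traj_ids, times = [], [], []
    for tr in range(settings.n_trajectories):
        cfg = dataclasses.replace(
            config,
            seed=seed + tr,
            max_time_ns=settings.duration_ns,
            snapshot_interval_ps=settings.interval_ns * 1000.0,
        )
        try:
            result = run(stripped, ff, cfg, event_groups=[], collect_frames=True)
        except Exception as exc:
            warnings.warn(f"randomization trajectory {tr} dropped: {exc}")
            continue
        for frame in result.frames:
            if frame.time_ns <= 0.0:
                continue
            members.append(frame.coords)
            traj_ids.append(tr)
            times.append(frame.time_ns)
    if len(members) < settings.n_trajectories * settings.members_per_trajectory:
        warnings.warn(
            f"ensemble smaller than requested: {len(members)} of "
            f"{settings.n_trajectories * settings.members_per_trajectory} members"
        )
    return EnsembleSet(
        members=members,
        trajectory_id=np.asarray(traj_ids, dtype=np.int64),
        sample_time_ns=np.asarray(times),
        settings=settings,
    )


# ---------------------------------------------------------------------------
# Event records and tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EventRecord:
    """Outcome of one binding-event trial."""

    trial: int
    seed: int
    initial_structure: int  # ensemble member index (-1 for explicit starts)
    site: str | None  # productive site id, None on timeout
    chain: str | None
    cis: bool | None
    elapsed_ns: float
    episodes: list = dataclasses.field(default_factory=list)

    @property
    def timed_out(self) -> bool:
        return self.site is None


@dataclasses.dataclass
class BindingEventTable:
    """Campaign-level tabulation of productive binding events."""

    counts: pd.DataFrame  # index site id, columns: cis, trans
    n_trials: int
    n_events: int
    n_timeouts: int
    total_simulated_ns: float

    @property
    def mean_event_time_ns(self) -> float:
        return self.total_simulated_ns / self.n_events if self.n_events else float("nan")

    def cis_total(self) -> int:
        return int(self.counts["cis"].sum())

    def trans_total(self) -> int:
        return int(self.counts["trans"].sum())

    def site_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def tabulate_events(records: Sequence[EventRecord]) -> BindingEventTable:
    """Aggregate event records; timeouts are excluded from frequency counts."""
    rows = {}
    n_events = n_timeouts = 0
    total_ns = 0.0
    for rec in records:
        total_ns += rec.elapsed_ns
        if rec.timed_out:
            n_timeouts += 1
            continue
        n_events += 1
        key = rec.site
        if key not in rows:
            rows[key] = {"cis": 0, "trans": 0}
        rows[key]["cis" if rec.cis else "trans"] += 1
    counts = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if counts.empty:
        counts = pd.DataFrame(columns=["cis", "trans"], dtype=int)
    else:
        for col in ("cis", "trans"):
            if col not in counts:
                counts[col] = 0
        counts = counts[["cis", "trans"]].sort_index()
    return BindingEventTable(
        counts=counts,
        n_trials=len(records),
        n_events=n_events,
        n_timeouts=n_timeouts,
        total_simulated_ns=total_ns,
    )


def events_frame(records: Sequence[EventRecord]) -> pd.DataFrame:
    """Per-event rows in the fixed TSV column order."""
    return pd.DataFrame(
        [
            {
                "trial": r.trial,
                "seed": r.seed,
                "site": r.site if r.site is not None else "timeout",
                "chain": r.chain if r.chain is not None else "-",
                "cis": int(bool(r.cis)) if r.cis is not None else -1,
                "elapsed_ns": r.elapsed_ns,
                "initial_structure": r.initial_structure,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Campaigns
# ---------------------------------------------------------------------------


def run_binding_campaign(
    ensemble: EnsembleSet | None,
    system: CGSystem,
    ff: GoForceField,
    config: IntegratorConfig,
    n_trials: int,
    seed: int = 0,
    timeout_ns: float = 5000.0,
    start_coords: Sequence[np.ndarray] | None = None,
    relax_starts: bool = True,
) -> tuple[BindingEventTable, list[EventRecord]]:
    """Iterative first-binding-event campaign.

    Each trial draws a start uniformly (with replacement, seeded as
    ``seed + trial``) from the ensemble -- or from ``start_coords`` when
    given -- and propagates the full system (P-site attractions restored)
    until a productive event or ``timeout_ns``.  Starts are relaxed by a
    short minimization by default: restoring attractions can leave a frame
    strained.
    """
    from .dynamics import minimize

    if start_coords is None and (ensemble is None or len(ensemble) == 0):
        raise ValueError("ensemble must be non-empty")
    compiled = compile_system(system, ff, config)
    relaxed_cache: dict[int, np.ndarray] = {}
    records = []
    for trial in range(n_trials):
        trial_seed = seed + trial
        rng = np.random.default_rng(trial_seed)
        if start_coords is not None:
            member = int(rng.integers(len(start_coords)))
            coords = start_coords[member]
            member_id = -1 - member
        else:
            member = int(rng.integers(len(ensemble)))
            coords = ensemble.members[member]
            member_id = member
        if relax_starts:
            if member_id not in relaxed_cache:
                relaxed_cache[member_id] = minimize(system, ff, coords)
            coords = relaxed_cache[member_id]
        cfg = dataclasses.replace(config, seed=trial_seed, max_time_ns=timeout_ns)
        result = run(system, ff, cfg, start_coords=coords, compiled=compiled, collect_frames=False)
        if result.terminated_by == "event":
            grp = result.event_group
            records.append(
                EventRecord(
                    trial=trial,
                    seed=trial_seed,
                    initial_structure=member_id,
                    site=grp.site_id,
                    chain=grp.psite_chain,
                    cis=grp.cis,
                    elapsed_ns=result.elapsed_ns,
                )
            )
        else:
            records.append(
                EventRecord(
                    trial=trial,
                    seed=trial_seed,
                    initial_structure=member_id,
                    site=None,
                    chain=None,
                    cis=None,
                    elapsed_ns=result.elapsed_ns,
                )
            )
    table = tabulate_events(records)
    if table.n_events == 0:
        warnings.warn("all trials timed out: empty event table")
    return table, records


def zero_ct_charges(system: CGSystem, tail_ranges: Sequence[tuple]) -> CGSystem:
    """Zero the charges of the named tail residue ranges (chain, first, last).

    Attractive terms are untouched; the operation is idempotent.
    """
    out = system.copy()
    top = out.topology
    for chain, first, last in tail_ranges:
        mask = (top.chain == chain) & (top.resid >= first) & (top.resid <= last)
        top.charge[mask] = 0.0
    return out


def mimic_phosphorylation(system: CGSystem, site_id: str, charge_delta: float = -1.0) -> CGSystem:
    """Mimic phosphorylation of one P-site copy.

    The site's tyrosine bead gains a formal negative charge and every
    attractive term involving the site's window residues is removed (both
    its catalytic-site and activator-site groups), so the site can no longer
    trigger an event.
    """
    matching = [g for g in system.psite_groups if g.site_id == site_id]
    if not matching:
        raise KeyError(f"unknown P-site {site_id!r}")
    out = system.copy()
    tyr = matching[0].tyr_bead
    out.topology.charge[tyr] += charge_delta
    window = set(int(b) for g in matching for b in g.window_beads)

    def keep(tag_idx):
        k = tag_idx
        if not out.contacts.tag[k].startswith("psite:"):
            return True
        return not (int(out.contacts.i[k]) in window or int(out.contacts.j[k]) in window)

    mask = np.array([keep(k) for k in range(len(out.contacts))], dtype=bool)
    out.contacts.i = out.contacts.i[mask]
    out.contacts.j = out.contacts.j[mask]
    out.contacts.sigma = out.contacts.sigma[mask]
    out.contacts.eps = out.contacts.eps[mask]
    out.contacts.tag = [t for t, m in zip(out.contacts.tag, mask) if m]
    for g in out.psite_groups:
        if g.site_id == site_id:
            g.enabled = False
    return out


def run_second_event_campaign(
    bound_states: Sequence[np.ndarray],
    system: CGSystem,
    ff: GoForceField,
    config: IntegratorConfig,
    first_site: str,
    n_trials: int,
    seed: int = 0,
    timeout_ns: float = 5000.0,
) -> tuple[BindingEventTable, list[EventRecord]]:
    """Second-binding-event campaign after phosphorylation of ``first_site``.

    Starts are bound-state structures for the first site; its
    phosphorylation is mimicked, so each trial begins with the release of
    the phosphorylated site and runs until another P-site binds.
    """
    if not len(bound_states):
        raise ValueError("need at least one bound-state start structure")
    modified = mimic_phosphorylation(system, first_site)
    return run_binding_campaign(
        None, modified, ff, config, n_trials, seed=seed, timeout_ns=timeout_ns,
        start_coords=list(bound_states),
    )


def run_tether_comparison(
    ff: GoForceField,
    config: IntegratorConfig,
    seed: int = 0,
    tethers: tuple = (10, 60),
    n_trials: int = 140,
    timeout_ns: float = 12.0,
    ensemble_settings: EnsembleSettings | None = None,
) -> dict:
    """Sequence-proximity experiment on a toy dimer.

    A single toy dimer carries two otherwise identical P-sites per chain,
    tethered at the two given sequence distances from the fold, competing
    within each trial -- mirroring how sites of one CT tail compete for the
    catalytic site.  The kinase-proximal site is expected to accumulate
    more cis events; the comparison of the per-site cis counts is reported
    with an exact sign-test p-value.
    """
    from .analysis import cis_trans_test
    from .fixtures import ToyDimerSpec, make_toy_dimer

    ensemble_settings = ensemble_settings or EnsembleSettings(5, 60.0, 2.0)
    system = make_toy_dimer(
        ToyDimerSpec(psite_tethers={"A": list(tethers), "B": list(tethers)})
    )
    ens = randomize_ensemble(system, ff, config, ensemble_settings, seed=seed + 1)
    table, records = run_binding_campaign(
        ens, system, ff, config, n_trials=n_trials, seed=seed, timeout_ns=timeout_ns,
    )
    # per-chain site ids: the cis copies live on the receiver chain
    receiver = next(g.target_chain for g in system.productive_groups())
    groups = [g for g in system.productive_groups() if g.psite_chain == receiver]
    by_tether = {g.tyr_bead: g.site_id for g in groups}
    ordered = [by_tether[b] for b in sorted(by_tether)]  # ascending tether
    out = {
        "tethers": tethers,
        "n_trials": n_trials,
        "timeout_ns": timeout_ns,
        "events": table.n_events,
        "timeouts": table.n_timeouts,
        "mean_event_time_ns": table.mean_event_time_ns,
    }
    cis_counts = []
    for label, site in zip(("short", "long"), ordered):
        cis = int(table.counts.loc[site, "cis"]) if site in table.counts.index else 0
        cis_counts.append(cis)
        out[label] = {"site": site, "cis": cis}
    if sum(cis_counts) > 0:
        out["cis_sign_test_p"] = cis_trans_test(cis_counts, seed=seed).p_value
    else:
        out["cis_sign_test_p"] = None
    return out


# ---------------------------------------------------------------------------
# Nonproductive activator-site binding episodes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BindingEpisode:
    site: str
    entry_ns: float
    exit_ns: float


def monitor_nonproductive_binding(
    times_ns: np.ndarray,
    distances: dict,
    threshold: float = 12.0,
    dwell_ns: float = 1.0,
) -> list[BindingEpisode]:
    """Segment tyrosine/activator-site distance traces into binding episodes.

    An episode opens when a site's distance to the activator-site anchor
    stays at or below ``threshold`` continuously for at least ``dwell_ns``
    and closes on a sustained (>= dwell) exit; excursions shorter than the
    dwell in either direction are debounced away.  Episodes are returned in
    entry-time order.
    """
    times_ns = np.asarray(times_ns, dtype=float)
    episodes: list[BindingEpisode] = []
    for site, trace in distances.items():
        trace = np.asarray(trace, dtype=float)
        below = trace <= threshold
        state_open = False
        run_start = None
        entry = None
        for k, t in enumerate(times_ns):
            if not state_open:
                if below[k]:
                    if run_start is None:
                        run_start = t
                    if t - run_start >= dwell_ns:
                        state_open = True
                        entry = run_start
                        run_start = None
                else:
                    run_start = None
            else:
                if not below[k]:
                    if run_start is None:
                        run_start = t
                    if t - run_start >= dwell_ns:
                        episodes.append(BindingEpisode(site, entry, run_start))
                        state_open = False
                        run_start = None
                else:
                    run_start = None
        if state_open:
            episodes.append(BindingEpisode(site, entry, float(times_ns[-1])))
    episodes.sort(key=lambda e: e.entry_ns)
    return episodes
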