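"""Synthetic study datasets: roster, sightings, behaviour and agonistic logs.

The generator emulates the design of a photographic association study of two
large captive flamingo flocks: four samples a day on four consecutive days a
week over several months, partial identifiability (birds conceal their leg
rings), grouping preferences structured by a latent personality scalar, sex,
origin and age, persistent preferred-companion bonds, and personality-linked
fight, win and social-support rates. Every pipeline stage is therefore
testable end to end without any field data, and the latent ground truth is
returned alongside the observable streams.

Group composition per sample uses sequential seating: birds are placed one by
one and join an existing subgroup with probability proportional to
``size * exp(mean affinity to its members)`` or open a new subgroup with a
concentration weight chosen so the expected number of subgroups matches the
configured mean subgroup size. With all affinity weights at zero the process
reduces to a plain Chinese-restaurant partition, which is exchangeable over
bird identities — the natural null for calibration studies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .types import (
    UNIDENTIFIED,
    AgonisticEvent,
    BehaviourEvent,
    BirdRecord,
    Participant,
    ProximityRecord,
    SightingSession,
    Subgroup,
    SupportRecord,
)

__all__ = ["SimConfig", "SyntheticDataset", "generate_dataset", "sessions_to_proximity"]

_SLOTS = ("1000", "1200", "1500", "1630")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are sized to a single study flock: ~140 birds observed in 4
    photographic samples a day on 4 consecutive days a week for ~5 months
    (69 observation days), a mean subgroup size of 10 birds, a 15% chance per
    sighting that a bird's ring is concealed, and a small cohort of birds
    added about 60% of the way through the study. Homophily weights act on
    the affinity scale (log group-joining weight); slopes act on log event
    rates (fights, behaviours) or logits (wins, support).
    """

    n_birds: int = 140
    n_days: int = 69
    sessions_per_day: int = 4
    mean_group_size: float = 10.0
    # affinity structure
    w_personality: float = 0.5
    w_sex: float = 0.4
    w_origin: float = 0.4
    w_age: float = 0.03
    pair_fidelity: float = 2.5
    bond_frac: float = 0.6
    concealment_prob: float = 0.15
    # roster composition
    sex_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)  # male, female, unknown
    origin_probs: tuple[float, float] = (0.5, 0.5)  # wild, captive
    age_range: tuple[float, float] = (2.0, 45.0)
    late_addition_frac: float = 0.09
    # behavioural event rates: per-trait (base mean count, slope on z)
    behaviour_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "aggressive": (20.0, 0.2),
            "exploratory": (10.0, 0.2),
            "submissive": (15.0, 0.2),
        }
    )
    # agonistic structure
    fight_base_rate: float = 6.0  # expected instigations per bird over the study
    fight_rate_slope: float = 0.5
    win_logit_slope: float = 1.0
    draw_prob: float = 0.1
    support_base_logit: float = -0.5
    support_prob_slope: float = 0.8
    displaced_frac: float = 0.2
    agonistic_concealment: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_birds < 4:
            raise ValueError("n_birds must be >= 4")
        if self.mean_group_size <= 1:
            raise ValueError("mean_group_size must exceed 1")
        if not 0 <= self.concealment_prob < 1:
            raise ValueError("concealment_prob must lie in [0, 1)")
        for name in ("draw_prob", "displaced_frac", "bond_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.w_personality, self.w_sex, self.w_origin, self.w_age) < 0:
            raise ValueError("homophily weights must be >= 0")
        if self.pair_fidelity < 0:
            raise ValueError("pair_fidelity must be >= 0")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Reduced profile (30 birds, 20 days) for fast pipeline exercises."""
        base = dict(
            n_birds=30,
            n_days=20,
            mean_group_size=5.0,
            late_addition_frac=0.0,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def strong(self, **overrides) -> "SimConfig":
        """Copy with unambiguously strong homophily and personality effects.

        Used for direction/power studies: personality homophily and companion
        fidelity dominate grouping, trait tallies track the latent scalar
        tightly, and fight/support rates rise steeply with it.
        """
        boosted = dict(
            w_personality=2.0,
            pair_fidelity=3.0,
            behaviour_rates={
                k: (b, 0.5) for k, (b, _) in self.behaviour_rates.items()
            },
            fight_base_rate=15.0,
            fight_rate_slope=1.0,
            win_logit_slope=1.0,
            support_base_logit=0.0,
            support_prob_slope=3.0,
            displaced_frac=0.1,
        )
        boosted.update(overrides)
        return dataclasses.replace(self, **boosted)

    def null(self, **overrides) -> "SimConfig":
        """Copy with every homophily weight and effect slope set to zero."""
        zeroed = dict(
            w_personality=0.0,
            w_sex=0.0,
            w_origin=0.0,
            w_age=0.0,
            pair_fidelity=0.0,
            fight_rate_slope=0.0,
            win_logit_slope=0.0,
            support_prob_slope=0.0,
            behaviour_rates={k: (b, 0.0) for k, (b, _) in self.behaviour_rates.items()},
        )
        zeroed.update(overrides)
        return dataclasses.replace(self, **zeroed)


@dataclass
class SyntheticDataset:
    roster: list[BirdRecord]
    sessions: list[SightingSession]
    behaviour_events: list[BehaviourEvent]
    agonistic_events: list[AgonisticEvent]
    ground_truth: dict

    def write(self, outdir: str | Path) -> None:
        """Emit the pipeline's CSV dialects plus a ground-truth YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_roster(self.roster, outdir / "roster.csv")
        fio.write_sightings(self.sessions, outdir / "sightings.csv")
        fio.write_behaviour_events(self.behaviour_events, outdir / "behaviour.csv")
        fio.write_agonistic_events(
            self.agonistic_events, outdir / "fights.csv", outdir / "supports.csv"
        )
        gt = dict(self.ground_truth)
        gt.pop("affinity", None)  # full matrix stays in memory only
        gt["z"] = {k: float(v) for k, v in gt["z"].items()}
        gt["bonds"] = [list(b) for b in gt["bonds"]]
        with open(outdir / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(gt, fh, sort_keys=True)


def observation_days(n_days: int) -> list[int]:
    """Day indices following the 4-consecutive-days-a-week sampling calendar."""
    days = []
    week = 0
    while len(days) < n_days:
        for d in range(4):
            if len(days) == n_days:
                break
            days.append(7 * week + d)
        week += 1
    return days


def _crp_alpha(n: int, target_groups: float) -> float:
    """Concentration giving E[#groups] = target under the seating process."""
    lo, hi = 1e-6, 1e6

    def expected(a: float) -> float:
        return float(np.sum(a / (a + np.arange(n))))

    for _ in range(80):
        mid = (lo * hi) ** 0.5
        if expected(mid) < target_groups:
            lo = mid
        else:
            hi = mid
    return (lo * hi) ** 0.5


def generate_roster(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[BirdRecord], np.ndarray]:
    """Roster with sexes, origins, ages and first-day indices, plus latent z."""
    ids = [f"B{i:03d}" for i in range(cfg.n_birds)]
    sexes = rng.choice(["male", "female", "unknown"], size=cfg.n_birds, p=cfg.sex_probs)
    origins = rng.choice(["wild", "captive"], size=cfg.n_birds, p=cfg.origin_probs)
    ages = rng.uniform(*cfg.age_range, size=cfg.n_birds).round(1)
    days = observation_days(cfg.n_days)
    n_late = int(round(cfg.late_addition_frac * cfg.n_birds))
    first = np.zeros(cfg.n_birds, dtype=int)
    if n_late:
        join_day = days[int(0.6 * len(days))]
        late = rng.choice(cfg.n_birds, size=n_late, replace=False)
        first[late] = join_day
    z = rng.standard_normal(cfg.n_birds)
    roster = [
        BirdRecord(
            bird_id=ids[i],
            sex=str(sexes[i]),
            origin=str(origins[i]),
            age=float(ages[i]),
            first_day_present=int(first[i]),
        )
        for i in range(cfg.n_birds)
    ]
    return roster, z


def _affinity(
    cfg: SimConfig, roster: list[BirdRecord], z: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    n = cfg.n_birds
    ages = np.array([r.age for r in roster])
    sexes = np.array([r.sex for r in roster])
    origins = np.array([r.origin for r in roster])
    a = (
        -cfg.w_personality * np.abs(z[:, None] - z[None, :])
        - cfg.w_sex * (sexes[:, None] != sexes[None, :])
        - cfg.w_origin * (origins[:, None] != origins[None, :])
        - cfg.w_age * np.abs(ages[:, None] - ages[None, :])
    )
    bonds: list[tuple[str, str]] = []
    if cfg.pair_fidelity > 0 and cfg.bond_frac > 0:
        n_bonded = int(cfg.bond_frac * n) // 2 * 2
        chosen = rng.choice(n, size=n_bonded, replace=False)
        for k in range(0, n_bonded, 2):
            i, j = int(chosen[k]), int(chosen[k + 1])
            a[i, j] += cfg.pair_fidelity
            a[j, i] += cfg.pair_fidelity
            bonds.append((roster[i].bird_id, roster[j].bird_id))
    np.fill_diagonal(a, 0.0)
    return a, bonds


def _seat_session(
    eligible: np.ndarray,
    affinity: np.ndarray | None,
    alpha: float,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Partition the eligible birds by sequential (restaurant-style) seating."""
    order = rng.permutation(eligible)
    groups: list[list[int]] = []
    for b in order:
        if not groups:
            groups.append([int(b)])
            continue
        if affinity is None:
            weights = np.array([len(g) for g in groups], dtype=float)
        else:
            arow = affinity[b]
            weights = np.array(
                [len(g) * np.exp(arow[g].mean()) for g in groups], dtype=float
            )
        total = weights.sum() + alpha
        u = rng.random() * total
        c = np.cumsum(weights)
        k = int(np.searchsorted(c, u))
        if k == len(groups):
            groups.append([int(b)])
        else:
            groups[k].append(int(b))
    return groups


def generate_sightings(
    cfg: SimConfig,
    roster: list[BirdRecord],
    affinity: np.ndarray,
    rng: np.random.Generator,
) -> list[SightingSession]:
    """Sighting sessions with affinity-structured subgroups and concealment."""
    ids = [r.bird_id for r in roster]
    first = np.array([r.first_day_present for r in roster])
    uniform = not np.any(affinity)
    days = observation_days(cfg.n_days)
    sessions: list[SightingSession] = []
    alpha_cache: dict[int, float] = {}
    for day in days:
        eligible = np.flatnonzero(first <= day)
        ne = len(eligible)
        if ne not in alpha_cache:
            alpha_cache[ne] = _crp_alpha(ne, max(1.0, ne / cfg.mean_group_size))
        alpha = alpha_cache[ne]
        for slot in _SLOTS[: cfg.sessions_per_day]:
            groups = _seat_session(
                eligible, None if uniform else affinity, alpha, rng
            )
            subgroups = []
            for g in groups:
                if cfg.concealment_prob > 0:
                    hidden = rng.random(len(g)) < cfg.concealment_prob
                else:
                    hidden = np.zeros(len(g), dtype=bool)
                members = frozenset(ids[b] for b, h in zip(g, hidden) if not h)
                n_unid = int(hidden.sum())
                if members or n_unid:
                    subgroups.append(Subgroup(members, n_unid))
            sessions.append(SightingSession(day=day, slot=slot, subgroups=tuple(subgroups)))
    return sessions


def generate_behaviour_events(
    cfg: SimConfig,
    roster: list[BirdRecord],
    z: np.ndarray,
    rng: np.random.Generator,
) -> list[BehaviourEvent]:
    """Trait-linked behaviour counts with log-rates linear in the latent scalar.

    A shared positive slope on z induces the positive inter-correlation of
    the three tallies that motivates condensing them into one score.
    """
    days = observation_days(cfg.n_days)
    events: list[BehaviourEvent] = []
    for trait, (base, slope) in cfg.behaviour_rates.items():
        rates = base * np.exp(slope * z)
        counts = rng.poisson(rates)
        for i, c in enumerate(counts):
            if c == 0:
                continue
            for day in rng.choice(days, size=int(c)):
                events.append(
                    BehaviourEvent(bird_id=roster[i].bird_id, day=int(day), trait=trait)
                )
    events.sort(key=lambda e: (e.day, e.bird_id, e.trait))
    return events


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_agonistic_events(
    cfg: SimConfig,
    roster: list[BirdRecord],
    z: np.ndarray,
    affinity: np.ndarray,
    rng: np.random.Generator,
) -> list[AgonisticEvent]:
    """Fights with personality-linked instigation, outcome and support.

    Per fight: an instigator is drawn with probability proportional to
    exp(fight_rate_slope * z), the opponent uniformly; the instigator wins
    with logistic probability in (z_i - z_j) unless the fight is a draw; a
    potential supporter is recruited from the focal bird's high-affinity
    neighbours and joins with probability increasing in its own z. A
    configurable fraction of support acts ends with the focal bird displaced,
    which disqualifies the record under the counting rule.
    """
    ids = [r.bird_id for r in roster]
    first = np.array([r.first_day_present for r in roster])
    days = observation_days(cfg.n_days)
    n_fights = rng.poisson(cfg.fight_base_rate * cfg.n_birds)
    events: list[AgonisticEvent] = []
    for f in range(n_fights):
        day = int(rng.choice(days))
        eligible = np.flatnonzero(first <= day)
        if len(eligible) < 3:
            continue
        w = np.exp(cfg.fight_rate_slope * z[eligible])
        i = int(rng.choice(eligible, p=w / w.sum()))
        j = int(rng.choice(eligible[eligible != i]))
        if rng.random() < cfg.draw_prob:
            out_i = out_j = "draw"
        elif rng.random() < _sigmoid(cfg.win_logit_slope * (z[i] - z[j])):
            out_i, out_j = "win", "loss"
        else:
            out_i, out_j = "loss", "win"
        participants = [
            Participant(ids[i], side="1", outcome=out_i),
            Participant(ids[j], side="2", outcome=out_j),
        ]
        supports: list[SupportRecord] = []
        focal = int(rng.choice([i, j]))
        side = "1" if focal == i else "2"
        cand_pool = eligible[(eligible != i) & (eligible != j)]
        if len(cand_pool):
            aw = np.exp(affinity[focal, cand_pool])
            s = int(rng.choice(cand_pool, p=aw / aw.sum()))
            if rng.random() < _sigmoid(cfg.support_base_logit + cfg.support_prob_slope * z[s]):
                outcome = out_i if side == "1" else out_j
                participants.append(Participant(ids[s], side=side, outcome=outcome))
                supports.append(
                    SupportRecord(
                        supporter_id=ids[s],
                        supported_id=ids[focal],
                        focal_displaced_after=bool(rng.random() < cfg.displaced_frac),
                    )
                )
        # observer occasionally fails to identify a participant
        relabel: dict[str, str] = {}
        if cfg.agonistic_concealment > 0:
            for p in participants:
                if rng.random() < cfg.agonistic_concealment:
                    relabel[p.bird_id] = UNIDENTIFIED
            if relabel:
                participants = [
                    dataclasses.replace(p, bird_id=relabel.get(p.bird_id, p.bird_id))
                    for p in participants
                ]
                supports = [
                    dataclasses.replace(
                        s,
                        supporter_id=relabel.get(s.supporter_id, s.supporter_id),
                        supported_id=relabel.get(s.supported_id, s.supported_id),
                    )
                    for s in supports
                ]
        instigator = relabel.get(ids[i], ids[i])
        events.append(
            AgonisticEvent(
                event_id=f"F{f:05d}",
                day=day,
                participants=tuple(participants),
                instigator_id=instigator,
                supports=tuple(supports),
            )
        )
    events.sort(key=lambda e: (e.day, e.event_id))
    return events


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate a complete, mutually consistent synthetic study dataset."""
    ss = np.random.SeedSequence(cfg.seed)
    r_roster, r_sight, r_beh, r_agon = (np.random.default_rng(s) for s in ss.spawn(4))
    roster, z = generate_roster(cfg, r_roster)
    affinity, bonds = _affinity(cfg, roster, z, r_roster)
    sessions = generate_sightings(cfg, roster, affinity, r_sight)
    behaviour = generate_behaviour_events(cfg, roster, z, r_beh)
    agonistic = generate_agonistic_events(cfg, roster, z, affinity, r_agon)
    ground_truth = {
        "z": {r.bird_id: float(zi) for r, zi in zip(roster, z)},
        "bonds": bonds,
        "affinity": affinity,
        "slopes": {
            "fight_rate_slope": cfg.fight_rate_slope,
            "win_logit_slope": cfg.win_logit_slope,
            "support_prob_slope": cfg.support_prob_slope,
        },
        "seed": cfg.seed,
    }
    return SyntheticDataset(
        roster=roster,
        sessions=sessions,
        behaviour_events=behaviour,
        agonistic_events=agonistic,
        ground_truth=ground_truth,
    )


def sessions_to_proximity(
    sessions: list[SightingSession], seed: int | None = None
) -> list[ProximityRecord]:
    """Export identified subgroup members as one-neck-length proximity chains.

    Each subgroup becomes a random spanning path over its identified members,
    so re-deriving groups through the chain rule recovers the partition
    exactly. Unidentified counts cannot be expressed as proximity edges and
    are dropped.
    """
    rng = np.random.default_rng(seed)
    records = []
    for s in sessions:
        edges: set[frozenset[str]] = set()
        sighted: set[str] = set()
        for g in s.subgroups:
            members = sorted(g.member_ids)
            sighted |= set(members)
            if len(members) >= 2:
                order = rng.permutation(len(members))
                for a, b in zip(order[:-1], order[1:]):
                    edges.add(frozenset((members[a], members[b])))
        records.append(
            ProximityRecord(
                day=s.day,
                slot=s.slot,
                edges=frozenset(edges),
                sighted_ids=frozenset(sighted),
            )
        )
    return records
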