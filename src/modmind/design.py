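"""Study designs and observation data for multi-species cognitive task batteries.

A :class:`StudyDesign` is the fixed skeleton shared by the synthetic-data
generator and the sampler: which species were tested (with how many
subjects), which tasks exist, how tasks group into cognitive domains, how
many scored trials each task has, and which (subject, task) pairs were
actually observed.  A :class:`Dataset` holds the observations themselves in
long format: per-trial binary outcomes for binomial-response tasks and one
real-valued score per subject for rank-response tasks (ratio or
indifference-point measures that only enter the model through their
within-task rank ordering).

:func:`paper_design` builds the battery this package was written around:
7 primate species (99 subjects), 17 tasks in 4 domains (inhibition, memory,
transposition, support), with 3 rank-type tasks (IN1, IN2, IN5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import DatasetError, DatasetParseError, DesignError

__all__ = [
    "TaskDef",
    "StudyDesign",
    "Dataset",
    "RankVector",
    "paper_design",
    "six_domain_design",
    "thin_participation",
    "scores_to_ranks",
    "read_dataset",
    "write_dataset",
    "design_to_yaml",
    "design_from_yaml",
]

RESPONSE_TYPES = ("binomial", "rank")

#: (task_id, domain, response_type, n_trials) for the 17-task battery.
#: Trial counts: 2 trials in IN3, TR1 and TR2; 10 in IN4; 3 in ME1 and ME2;
#: 1 in TR3 and TR4; 6 in each support task.  IN1/IN2 (experimental/control
#: ratio scores) and IN5 (indifference point) are rank-type.
PAPER_TASK_TABLE = (
    ("IN1", "inhibition", "rank", 1),
    ("IN2", "inhibition", "rank", 1),
    ("IN3", "inhibition", "binomial", 2),
    ("IN4", "inhibition", "binomial", 10),
    ("IN5", "inhibition", "rank", 1),
    ("ME1", "memory", "binomial", 3),
    ("ME2", "memory", "binomial", 3),
    ("TR1", "transposition", "binomial", 2),
    ("TR2", "transposition", "binomial", 2),
    ("TR3", "transposition", "binomial", 1),
    ("TR4", "transposition", "binomial", 1),
    ("SU1", "support", "binomial", 6),
    ("SU2", "support", "binomial", 6),
    ("SU3", "support", "binomial", 6),
    ("SU4", "support", "binomial", 6),
    ("SU5", "support", "binomial", 6),
    ("SU6", "support", "binomial", 6),
)

#: Species codes with subject counts: chimpanzees, bonobos, orangutans,
#: gorillas, spider monkeys, brown capuchin monkeys, long-tailed macaques.
PAPER_SPECIES_COUNTS = (
    ("CH", 19),
    ("BO", 5),
    ("OR", 10),
    ("GO", 8),
    ("SM", 18),
    ("CM", 27),
    ("LM", 12),
)


@dataclass(frozen=True)
class TaskDef:
    """One task: identifier, domain, response type and number of scored trials."""

    task_id: str
    domain_id: str
    response_type: str
    n_trials: int

    def __post_init__(self):
        if self.response_type not in RESPONSE_TYPES:
            raise DesignError(
                f"task {self.task_id}: response_type must be one of {RESPONSE_TYPES}"
            )
        if self.n_trials < 1:
            raise DesignError(f"task {self.task_id}: n_trials must be >= 1")
        if self.response_type == "rank" and self.n_trials != 1:
            raise DesignError(f"rank task {self.task_id} must have n_trials == 1")


@dataclass(frozen=True)
class StudyDesign:
    """Fixed skeleton of a study: species, subjects, tasks, domains, participation.

    Parameters
    ----------
    species
        Ordered species labels.
    subjects
        ``(subject_id, species)`` pairs; every subject belongs to exactly
        one species.
    tasks
        Task definitions; each task belongs to exactly one domain.
    participation
        The ``(subject_id, task_id)`` pairs actually observed.  Explicit
        rather than inferred, because not all subjects were tested in each
        task and generators must be able to emulate that.
    """

    species: tuple[str, ...]
    subjects: tuple[tuple[str, str], ...]
    tasks: tuple[TaskDef, ...]
    participation: frozenset[tuple[str, str]]

    def __post_init__(self):
        sids = [s for s, _ in self.subjects]
        if len(set(sids)) != len(sids):
            raise DesignError("duplicate subject ids")
        tids = [t.task_id for t in self.tasks]
        if len(set(tids)) != len(tids):
            raise DesignError("duplicate task ids")
        if len(set(self.species)) != len(self.species):
            raise DesignError("duplicate species labels")
        for sid, sp in self.subjects:
            if sp not in self.species:
                raise DesignError(f"subject {sid} has unknown species {sp}")
        valid = {(sid, tid) for sid, _ in self.subjects for tid in tids}
        if not self.participation <= valid:
            bad = next(iter(self.participation - valid))
            raise DesignError(f"participation pair {bad} not in subjects x tasks")

    # -- convenience views -------------------------------------------------
    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.subjects)

    @property
    def task_ids(self) -> tuple[str, ...]:
        return tuple(t.task_id for t in self.tasks)

    @property
    def domain_map(self) -> dict[str, str]:
        return {t.task_id: t.domain_id for t in self.tasks}

    @property
    def domains(self) -> tuple[str, ...]:
        """Domains in order of first appearance in the task table."""
        seen: dict[str, None] = {}
        for t in self.tasks:
            seen.setdefault(t.domain_id, None)
        return tuple(seen)

    @property
    def species_of(self) -> dict[str, str]:
        return dict(self.subjects)

    def species_counts(self) -> dict[str, int]:
        counts = {sp: 0 for sp in self.species}
        for _, sp in self.subjects:
            counts[sp] += 1
        return counts

    def task(self, task_id: str) -> TaskDef:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise DesignError(f"unknown task {task_id}")

    def rank_task_ids(self) -> tuple[str, ...]:
        return tuple(t.task_id for t in self.tasks if t.response_type == "rank")

    def n_subjects(self) -> int:
        return len(self.subjects)

    def with_participation(self, pairs) -> "StudyDesign":
        return replace(self, participation=frozenset(pairs))

    def restrict_species(self, keep) -> "StudyDesign":
        keep = tuple(sp for sp in self.species if sp in set(keep))
        subjects = tuple((s, sp) for s, sp in self.subjects if sp in keep)
        sids = {s for s, _ in subjects}
        part = frozenset(p for p in self.participation if p[0] in sids)
        return StudyDesign(keep, subjects, self.tasks, part)


def _full_participation(subjects, tasks):
    return frozenset((sid, t.task_id) for sid, _ in subjects for t in tasks)


def paper_design() -> StudyDesign:
    """The 7-species / 99-subject / 17-task / 4-domain battery, full participation."""
    subjects = tuple(
        (f"{sp}{i:02d}", sp) for sp, n in PAPER_SPECIES_COUNTS for i in range(1, n + 1)
    )
    tasks = tuple(TaskDef(*row) for row in PAPER_TASK_TABLE)
    return StudyDesign(
        species=tuple(sp for sp, _ in PAPER_SPECIES_COUNTS),
        subjects=subjects,
        tasks=tasks,
        participation=_full_participation(subjects, tasks),
    )


#: Alternative 6-domain assignment: the inhibition domain split into a
#: cup/delay group (IN1, IN2, IN5) and a plexiglas-detour group (IN3, IN4);
#: the memory domain split into short-term (ME1) and long-term (ME2).
SIX_DOMAIN_MAP = {
    "IN1": "inhibition_a",
    "IN2": "inhibition_a",
    "IN5": "inhibition_a",
    "IN3": "inhibition_b",
    "IN4": "inhibition_b",
    "ME1": "memory_short",
    "ME2": "memory_long",
    "TR1": "transposition",
    "TR2": "transposition",
    "TR3": "transposition",
    "TR4": "transposition",
    "SU1": "support",
    "SU2": "support",
    "SU3": "support",
    "SU4": "support",
    "SU5": "support",
    "SU6": "support",
}


def six_domain_design() -> StudyDesign:
    """Same subjects/tasks as :func:`paper_design` under the 6-domain assignment."""
    base = paper_design()
    tasks = tuple(replace(t, domain_id=SIX_DOMAIN_MAP[t.task_id]) for t in base.tasks)
    return replace(base, tasks=tasks)


def thin_participation(design: StudyDesign, drop_fraction: float, seed: int) -> StudyDesign:
    """Randomly drop a fraction of (subject, task) pairs, emulating unbalanced testing.

    Every subject keeps at least one task and every task at least two
    subjects, so downstream ranking and effect updates stay well defined.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise DesignError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pairs = sorted(design.participation)
    keep = set(pairs)
    candidates = rng.permutation(len(pairs))
    n_drop = int(round(drop_fraction * len(pairs)))
    subj_count = {sid: 0 for sid in design.subject_ids}
    task_count = {tid: 0 for tid in design.task_ids}
    for sid, tid in pairs:
        subj_count[sid] += 1
        task_count[tid] += 1
    dropped = 0
    for idx in candidates:
        if dropped >= n_drop:
            break
        sid, tid = pairs[idx]
        if subj_count[sid] > 1 and task_count[tid] > 2:
            keep.discard((sid, tid))
            subj_count[sid] -= 1
            task_count[tid] -= 1
            dropped += 1
    return design.with_participation(keep)


@dataclass(frozen=True)
class Dataset:
    """Long-format observations bound to a design.

    ``binomial_obs`` maps ``(subject_id, task_id, trial_index)`` to a 0/1
    outcome; ``score_obs`` maps ``(subject_id, task_id)`` to the real score
    of a rank-type task.  Construction validates every observation against
    the design (response type, trial bounds, participation).
    """

    design: StudyDesign
    binomial_obs: dict[tuple[str, str, int], int] = field(default_factory=dict)
    score_obs: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        tasks = {t.task_id: t for t in self.design.tasks}
        part = self.design.participation
        for (sid, tid, trial), y in self.binomial_obs.items():
            t = tasks.get(tid)
            if t is None:
                raise DatasetError(f"unknown task {tid}")
            if t.response_type != "binomial":
                raise DatasetError(f"task {tid} is not binomial")
            if not 0 <= trial < t.n_trials:
                raise DatasetError(f"trial_index {trial} out of range for task {tid}")
            if y not in (0, 1):
                raise DatasetError(f"outcome {y!r} not in {{0, 1}}")
            if (sid, tid) not in part:
                raise DatasetError(f"observation outside participation: {(sid, tid)}")
        for (sid, tid), x in self.score_obs.items():
            t = tasks.get(tid)
            if t is None:
                raise DatasetError(f"unknown task {tid}")
            if t.response_type != "rank":
                raise DatasetError(f"task {tid} is not rank-type")
            if not math.isfinite(x):
                raise DatasetError(f"non-finite score for {(sid, tid)}")
            if (sid, tid) not in part:
                raise DatasetError(f"observation outside participation: {(sid, tid)}")

    def n_observations(self) -> int:
        return len(self.binomial_obs) + len(self.score_obs)

    def observed_pairs(self) -> frozenset[tuple[str, str]]:
        pairs = {(s, t) for (s, t, _) in self.binomial_obs}
        pairs |= set(self.score_obs)
        return frozenset(pairs)

    def filter_species(self, keep) -> "Dataset":
        """Restrict to a subset of species (used by the subset re-analysis)."""
        design = self.design.restrict_species(keep)
        sids = set(design.subject_ids)
        return Dataset(
            design=design,
            binomial_obs={k: v for k, v in self.binomial_obs.items() if k[0] in sids},
            score_obs={k: v for k, v in self.score_obs.items() if k[0] in sids},
        )


@dataclass(frozen=True)
class RankVector:
    """Weak ordering of subjects within one rank-type task (rank 1 = best)."""

    task_id: str
    ranks: dict[str, int]

    def groups(self) -> list[list[str]]:
        """Subjects grouped by rank, best first; tied subjects share a group."""
        by_rank: dict[int, list[str]] = {}
        for sid, r in self.ranks.items():
            by_rank.setdefault(r, []).append(sid)
        return [sorted(by_rank[r]) for r in sorted(by_rank)]


def scores_to_ranks(dataset: Dataset, task_id: str) -> RankVector:
    """Reduce a rank-task's scores to competition ranks (descending; ties share).

    Higher score = better performance = rank 1.  Exactly tied scores get
    equal ranks ("1, 1, 3"); the downstream rank likelihood consumes only
    the weak ordering, so any tie convention yielding the same ordering is
    equivalent.  Invariant under strictly increasing transforms of scores.
    """
    task = dataset.design.task(task_id)
    if task.response_type != "rank":
        raise DatasetError(f"task {task_id} is not rank-type")
    scores = {
        sid: x for (sid, tid), x in dataset.score_obs.items() if tid == task_id
    }
    if not scores:
        raise DatasetError(f"no scores observed for task {task_id}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks: dict[str, int] = {}
    prev_score: float | None = None
    prev_rank = 0
    for pos, (sid, x) in enumerate(ordered, start=1):
        if prev_score is not None and x == prev_score:
            ranks[sid] = prev_rank
        else:
            ranks[sid] = pos
            prev_rank = pos
            prev_score = x
    return RankVector(task_id=task_id, ranks=ranks)


# ---------------------------------------------------------------------------
# Serialization: observations CSV and design YAML
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["subject_id", "species", "task_id", "trial_index", "outcome", "score"]


def write_dataset(dataset: Dataset, path) -> None:
    """Write observations to CSV (UTF-8, header, 0-based trial_index).

    Exactly one of ``outcome`` / ``score`` is non-empty per row; scores are
    written with full ``repr`` precision so the round trip is exact.
    """
    species_of = dataset.design.species_of
    rows = []
    for (sid, tid, trial), y in sorted(dataset.binomial_obs.items()):
        rows.append((sid, species_of[sid], tid, str(trial), str(int(y)), ""))
    for (sid, tid), x in sorted(dataset.score_obs.items()):
        rows.append((sid, species_of[sid], tid, "", "", repr(float(x))))
    rows.sort(key=lambda r: (r[0], r[2], r[3]))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_dataset(path, design: StudyDesign | None = None) -> Dataset:
    """Read an observations CSV; parse errors name the offending file row.

    The design supplies task metadata the CSV does not carry (trial counts,
    domains); defaults to :func:`paper_design`.  The returned dataset's
    participation is the set of pairs actually present in the file.
    """
    if design is None:
        design = paper_design()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetParseError(f"missing columns {missing}")
    tasks = {t.task_id: t for t in design.tasks}
    species_of = design.species_of
    binomial_obs: dict[tuple[str, str, int], int] = {}
    score_obs: dict[tuple[str, str], float] = {}
    pairs: set[tuple[str, str]] = set()
    for i, rec in enumerate(df.itertuples(index=False)):
        row = i + 2  # 1-based file line, after the header
        sid, sp, tid = rec.subject_id, rec.species, rec.task_id
        if sid not in species_of:
            raise DatasetParseError(f"unknown subject_id {sid!r}", row)
        if species_of[sid] != sp:
            raise DatasetParseError(
                f"subject {sid} has species {species_of[sid]}, file says {sp!r}", row
            )
        task = tasks.get(tid)
        if task is None:
            raise DatasetParseError(f"unknown task_id {tid!r}", row)
        has_outcome = rec.outcome != ""
        has_score = rec.score != ""
        if has_outcome == has_score:
            raise DatasetParseError(
                "exactly one of outcome/score must be set", row
            )
        if has_outcome:
            if task.response_type != "binomial":
                raise DatasetParseError(f"task {tid} is rank-type, got an outcome", row)
            if rec.outcome not in ("0", "1"):
                raise DatasetParseError(f"outcome {rec.outcome!r} not in {{0, 1}}", row)
            try:
                trial = int(rec.trial_index)
            except ValueError:
                raise DatasetParseError(
                    f"bad trial_index {rec.trial_index!r}", row
                ) from None
            if not 0 <= trial < task.n_trials:
                raise DatasetParseError(
                    f"trial_index {trial} >= n_trials={task.n_trials} for {tid}", row
                )
            key = (sid, tid, trial)
            if key in binomial_obs:
                raise DatasetParseError(f"duplicate observation {key}", row)
            binomial_obs[key] = int(rec.outcome)
        else:
            if task.response_type != "rank":
                raise DatasetParseError(f"task {tid} is binomial, got a score", row)
            try:
                x = float(rec.score)
            except ValueError:
                raise DatasetParseError(f"bad score {rec.score!r}", row) from None
            key2 = (sid, tid)
            if key2 in score_obs:
                raise DatasetParseError(f"duplicate score for {key2}", row)
            score_obs[key2] = x
        pairs.add((sid, tid))
    return Dataset(
        design=design.with_participation(pairs),
        binomial_obs=binomial_obs,
        score_obs=score_obs,
    )


def design_to_yaml(design: StudyDesign, path) -> None:
    doc = {
        "species": list(design.species),
        "subjects": [{"subject_id": s, "species": sp} for s, sp in design.subjects],
        "tasks": [
            {
                "task_id": t.task_id,
                "domain": t.domain_id,
                "response_type": t.response_type,
                "n_trials": int(t.n_trials),
            }
            for t in design.tasks
        ],
        "participation": sorted(list(p) for p in design.participation),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def design_from_yaml(path) -> StudyDesign:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        tasks = tuple(
            TaskDef(t["task_id"], t["domain"], t["response_type"], int(t["n_trials"]))
            for t in doc["tasks"]
        )
        subjects = tuple((s["subject_id"], s["species"]) for s in doc["subjects"])
        part = frozenset((sid, tid) for sid, tid in doc["participation"])
        return StudyDesign(tuple(doc["species"]), subjects, tasks, part)
    except (KeyError, TypeError) as exc:
        raise DesignError(f"malformed design document: {exc}") from exc
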