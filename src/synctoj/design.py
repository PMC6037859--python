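"""Mixed block/event-related fMRI design generation and optimization.

A run consists of 32 stimulation blocks (16 per task, order randomized).
Each 25-s stimulation block holds 9 events: 5 stimuli of 3 s separated by 4
fixation events whose durations are a permutation of {1, 2, 3, 4} s.  A 16-s
fixation block follows every two stimulation blocks, and a 4-s instruction
screen precedes every stimulation block.  Per task and run, each of the four
COA conditions (audio-leading extreme, physical synchrony, subject PSS,
video-leading extreme) is shown 20 times, distributed over the 16 same-task
blocks as 0 presentations in 4 blocks, 1 in 6, 2 in 4 and 3 in 2 — this
within-block jitter is what decorrelates the block-long (sustained) and
event-locked (transient) regressors enough for both to be estimable.

Many random sequences are generated and scored by GLM estimation efficiency
and by the mean absolute correlation between each transient regressor and
its same-task sustained regressor; the best candidate balances the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

__all__ = [
    "TASKS",
    "COA_CONDITIONS",
    "Event",
    "RunSequence",
    "BlockComposition",
    "DesignMatrix",
    "DesignScore",
    "assign_block_composition",
    "build_run_sequence",
    "canonical_hrf",
    "build_design_matrix",
    "design_efficiency",
    "sustained_transient_correlation",
    "optimize_design",
]

TASKS = ("SJ", "TOJ")
COA_CONDITIONS = ("A333", "SYNC0", "PSS", "V333")

N_STIM_BLOCKS = 32            # per run; half SJ, half TOJ
N_BLOCKS_PER_TASK = 16
STIM_DURATION_S = 3.0
N_STIM_PER_BLOCK = 5
INTRA_FIX_DURATIONS_S = (1.0, 2.0, 3.0, 4.0)
STIM_BLOCK_DURATION_S = 25.0  # 5*3 + 1+2+3+4
FIX_BLOCK_DURATION_S = 16.0
INSTRUCTION_DURATION_S = 4.0
#: per-condition presentation counts over the 16 same-task blocks
COMPOSITION_MULTISET = (0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 3, 3)


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    kind: str           # stimulus | intra_block_fixation | fixation_block | instruction
    task: str = "none"  # SJ | TOJ | none
    coa_condition: str = "none"  # A333 | SYNC0 | PSS | V333 | none


@dataclass(frozen=True)
class BlockComposition:
    """16 same-task blocks x 4 COA conditions matrix of presentation counts."""

    counts: np.ndarray  # (16, 4) int

    def validate(self) -> None:
        c = self.counts
        if c.shape != (N_BLOCKS_PER_TASK, len(COA_CONDITIONS)):
            raise ValueError(f"composition must be 16x4, got {c.shape}")
        if not (c.sum(axis=1) == N_STIM_PER_BLOCK).all():
            raise ValueError("every block must contain exactly 5 stimuli")
        for j in range(c.shape[1]):
            if tuple(sorted(c[:, j])) != COMPOSITION_MULTISET:
                raise ValueError(
                    f"condition column {j} count multiset is not {{0x4,1x6,2x4,3x2}}"
                )


@dataclass(frozen=True)
class RunSequence:
    """Timed event list for one fMRI run."""

    events: tuple[Event, ...]
    blocks: tuple[tuple[float, str], ...]  # (onset_s, task) of each 25-s stim block
    n_stim_blocks: int
    seed: int | None = None

    @property
    def duration_s(self) -> float:
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset_s + last.duration_s


@dataclass(frozen=True)
class DesignMatrix:
    """Time x regressor matrix sampled at the scan TR, with labelled columns."""

    values: np.ndarray        # (n_scans, 18)
    labels: tuple[str, ...]
    tr_s: float

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    @property
    def sustained_labels(self) -> tuple[str, ...]:
        return tuple(f"{t}_sustained" for t in TASKS)

    @property
    def transient_labels(self) -> tuple[str, ...]:
        return tuple(f"{t}_{c}" for t in TASKS for c in COA_CONDITIONS)

    @property
    def interest_labels(self) -> tuple[str, ...]:
        return self.sustained_labels + self.transient_labels


@dataclass(frozen=True)
class DesignScore:
    efficiency: float
    mean_st_corr: float
    combined: float
    candidate_seed: int


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def assign_block_composition(seed, max_restarts: int = 200) -> BlockComposition:
    """Randomly distribute 20 presentations of each condition over 16 blocks.

    Each condition's per-block counts are a permutation of
    {0,0,0,0, 1,1,1,1,1,1, 2,2,2,2, 3,3} and each block receives exactly 5
    stimuli.  Found by randomized depth-first search with backtracking over
    blocks; restarts with a fresh shuffle on (rare) dead ends.
    """
    rng = _as_rng(seed)
    n_cond = len(COA_CONDITIONS)

    for _ in range(max_restarts):
        # remaining[j][v] = how many blocks may still get count v of condition j
        remaining = [
            {v: COMPOSITION_MULTISET.count(v) for v in set(COMPOSITION_MULTISET)}
            for _ in range(n_cond)
        ]
        rows: list[tuple[int, ...]] = []

        def extend(row_idx: int) -> bool:
            if row_idx == N_BLOCKS_PER_TASK:
                return True
            choices = _row_choices(remaining, rng)
            for row in choices:
                for j, v in enumerate(row):
                    remaining[j][v] -= 1
                rows.append(row)
                if extend(row_idx + 1):
                    return True
                rows.pop()
                for j, v in enumerate(row):
                    remaining[j][v] += 1
            return False

        if extend(0):
            comp = BlockComposition(np.array(rows, dtype=int))
            comp.validate()
            return comp
    raise RuntimeError("block composition search failed; constraint system unsatisfied")


def _row_choices(remaining, rng) -> list[tuple[int, ...]]:
    """All 4-tuples summing to 5 drawn from the remaining per-condition pools,
    in random order."""
    out: list[tuple[int, ...]] = []

    def rec(j: int, prefix: tuple[int, ...], total: int) -> None:
        if j == len(remaining):
            if total == N_STIM_PER_BLOCK:
                out.append(prefix)
            return
        for v, n_left in remaining[j].items():
            if n_left > 0 and total + v <= N_STIM_PER_BLOCK:
                rec(j + 1, prefix + (v,), total + v)

    rec(0, (), 0)
    rng.shuffle(out)
    return out


def build_run_sequence(
    compositions: dict[str, BlockComposition], seed
) -> RunSequence:
    """Assemble one run from per-task block compositions.

    Block task order, within-block stimulus order and the intra-block
    fixation-duration permutation are all randomized.  Every stimulation
    block is preceded by a 4-s instruction screen, and a 16-s fixation block
    follows every two stimulation blocks.
    """
    rng = _as_rng(seed)
    for task in TASKS:
        if task not in compositions:
            raise ValueError(f"missing composition for task {task}")
        compositions[task].validate()

    task_order = [t for t in TASKS for _ in range(N_BLOCKS_PER_TASK)]
    rng.shuffle(task_order)

    events: list[Event] = []
    blocks: list[tuple[float, str]] = []
    next_row = {t: 0 for t in TASKS}
    t_cur = 0.0
    for i, task in enumerate(task_order):
        events.append(Event(t_cur, INSTRUCTION_DURATION_S, "instruction", task))
        t_cur += INSTRUCTION_DURATION_S

        blocks.append((t_cur, task))
        row = compositions[task].counts[next_row[task]]
        next_row[task] += 1
        stim_conditions = [
            COA_CONDITIONS[j] for j in range(len(COA_CONDITIONS)) for _ in range(row[j])
        ]
        rng.shuffle(stim_conditions)
        fix_durs = list(INTRA_FIX_DURATIONS_S)
        rng.shuffle(fix_durs)
        for k, cond in enumerate(stim_conditions):
            events.append(Event(t_cur, STIM_DURATION_S, "stimulus", task, cond))
            t_cur += STIM_DURATION_S
            if k < len(fix_durs):
                events.append(Event(t_cur, fix_durs[k], "intra_block_fixation", task))
                t_cur += fix_durs[k]

        if i % 2 == 1:  # fixation block after every pair of stimulation blocks
            events.append(Event(t_cur, FIX_BLOCK_DURATION_S, "fixation_block"))
            t_cur += FIX_BLOCK_DURATION_S

    seed_val = None
    return RunSequence(tuple(events), tuple(blocks), N_STIM_BLOCKS, seed_val)


def canonical_hrf(dt_s: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel, peak-normalized.

    Response gamma peaks near 5 s (shape 6, scale 1); undershoot gamma
    (shape 16, scale 1) is subtracted at a 1:6 peak ratio.
    """
    if not (0 < dt_s <= 1):
        raise ValueError("dt_s must be in (0, 1]")
    t = np.arange(0.0, length_s, dt_s)
    h = gamma_dist.pdf(t, a=6.0) - gamma_dist.pdf(t, a=16.0) / 6.0
    return h / h.max()


MICROTIME_DT_S = 0.1


def build_design_matrix(
    sequence: RunSequence,
    tr_s: float = 2.0,
    hrf: np.ndarray | None = None,
    dt_s: float = MICROTIME_DT_S,
) -> DesignMatrix:
    """Two-timescale design matrix: 18 columns per session.

    Sustained columns are HRF-convolved 25-s boxcars per task; the eight
    transient columns are HRF-convolved impulses at stimulus onsets per
    task x COA condition.  Nuisance columns: instruction boxcar, six motion
    placeholders (zero in synthetic sessions, kept so column indices match
    a realignment-corrected session), and the constant.  Neural signals are
    built at ``dt_s`` microtime resolution, convolved, then sampled at TR.
    """
    if not sequence.events:
        raise ValueError("empty sequence")
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if hrf is None:
        hrf = canonical_hrf(dt_s)

    n_scans = math.ceil(sequence.duration_s / tr_s)
    n_micro = int(round(n_scans * tr_s / dt_s))

    neural_labels = (
        [f"{t}_sustained" for t in TASKS]
        + [f"{t}_{c}" for t in TASKS for c in COA_CONDITIONS]
        + ["instruction"]
    )
    neural = np.zeros((n_micro, len(neural_labels)))
    col = {lab: j for j, lab in enumerate(neural_labels)}

    def micro(t: float) -> int:
        return int(round(t / dt_s))

    for onset, task in sequence.blocks:
        a, b = micro(onset), micro(onset + STIM_BLOCK_DURATION_S)
        neural[a:b, col[f"{task}_sustained"]] = 1.0
    for ev in sequence.events:
        if ev.kind == "stimulus":
            neural[micro(ev.onset_s), col[f"{ev.task}_{ev.coa_condition}"]] = 1.0
        elif ev.kind == "instruction":
            neural[micro(ev.onset_s) : micro(ev.onset_s + ev.duration_s), col["instruction"]] = 1.0

    convolved = fftconvolve(neural, hrf[:, None], axes=0)[:n_micro]
    scan_idx = np.rint(np.arange(n_scans) * tr_s / dt_s).astype(int)
    sampled = convolved[scan_idx]

    motion = np.zeros((n_scans, 6))
    constant = np.ones((n_scans, 1))
    values = np.hstack([sampled, motion, constant])
    labels = tuple(neural_labels + [f"motion{i+1}" for i in range(6)] + ["constant"])
    return DesignMatrix(values, labels, tr_s)


def _default_contrasts(X: DesignMatrix) -> list[np.ndarray]:
    """Unit contrasts on the 10 columns of interest."""
    out = []
    for lab in X.interest_labels:
        c = np.zeros(len(X.labels))
        c[X.labels.index(lab)] = 1.0
        out.append(c)
    return out


def design_efficiency(
    X: DesignMatrix, contrasts: Sequence[np.ndarray] | None = None
) -> float:
    """GLM estimation efficiency: mean over contrasts of 1 / (c' (X'X)^-1 c).

    All-zero columns (motion placeholders) are excluded; any other linear
    dependency among the columns a contrast touches is an error.
    """
    if contrasts is None:
        contrasts = _default_contrasts(X)
    V = X.values
    nonzero = np.flatnonzero(np.ptp(V, axis=0) > 0)
    # constant column has zero ptp but is genuinely nonzero
    const = np.flatnonzero((np.ptp(V, axis=0) == 0) & (np.abs(V).max(axis=0) > 0))
    keep = np.sort(np.concatenate([nonzero, const]))
    Vk = V[:, keep]
    xtx = Vk.T @ Vk
    rank = np.linalg.matrix_rank(xtx)
    if rank < Vk.shape[1]:
        _, r = np.linalg.qr(Vk)
        dep = [X.labels[keep[j]] for j in np.flatnonzero(np.abs(np.diag(r)) < 1e-8)]
        raise np.linalg.LinAlgError(f"design is rank-deficient; dependent columns: {dep}")
    xtx_inv = np.linalg.inv(xtx)

    effs = []
    for c in contrasts:
        c = np.asarray(c, dtype=float)
        if np.any(c[np.setdiff1d(np.arange(len(c)), keep)] != 0):
            raise ValueError("contrast weights a zero (dropped) column")
        ck = c[keep]
        effs.append(1.0 / float(ck @ xtx_inv @ ck))
    return float(np.mean(effs))


def sustained_transient_correlation(X: DesignMatrix) -> float:
    """Mean |Pearson r| between each transient column and the same-task
    sustained column (8 pairs), computed before high-pass filtering."""
    vals = []
    for task in TASKS:
        s = X.column(f"{task}_sustained")
        if s.std() == 0:
            raise ValueError(f"{task}_sustained column is constant")
        for cond in COA_CONDITIONS:
            tcol = X.column(f"{task}_{cond}")
            if tcol.std() == 0:
                raise ValueError(f"{task}_{cond} column is constant")
            r = np.corrcoef(s, tcol)[0, 1]
            vals.append(abs(r))
    return float(np.mean(vals))


def _make_candidate(seed: int, tr_s: float, hrf: np.ndarray) -> tuple[RunSequence, DesignMatrix]:
    rng = np.random.default_rng(seed)
    comps = {t: assign_block_composition(rng) for t in TASKS}
    seq = build_run_sequence(comps, rng)
    seq = RunSequence(seq.events, seq.blocks, seq.n_stim_blocks, seed)
    return seq, build_design_matrix(seq, tr_s=tr_s, hrf=hrf)


def optimize_design(
    n_candidates: int,
    master_seed: int,
    tr_s: float = 2.0,
    contrasts: Sequence[np.ndarray] | None = None,
) -> tuple[RunSequence, DesignScore, list[DesignScore]]:
    """Generate many random run sequences and keep the best.

    Candidates are scored by estimation efficiency and by the mean
    sustained-transient correlation; both are standardized across candidates
    and combined as z(efficiency) - z(correlation), favouring designs that
    are simultaneously efficient and decorrelated.  Returns the selected
    sequence, its score, and all candidate scores.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    hrf = canonical_hrf(MICROTIME_DT_S)
    seeds = np.random.SeedSequence(master_seed).generate_state(n_candidates)

    eff = np.empty(n_candidates)
    corr = np.empty(n_candidates)
    for i, s in enumerate(seeds):
        _, X = _make_candidate(int(s), tr_s, hrf)
        eff[i] = design_efficiency(X, contrasts)
        corr[i] = sustained_transient_correlation(X)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    combined = z(eff) - z(corr)
    scores = [
        DesignScore(float(eff[i]), float(corr[i]), float(combined[i]), int(seeds[i]))
        for i in range(n_candidates)
    ]
    best_i = int(np.argmax(combined))
    best_seq, _ = _make_candidate(int(seeds[best_i]), tr_s, hrf)
    return best_seq, scores[best_i], scores
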