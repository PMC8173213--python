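"""Subtype-and-stage inference for z-score event progressions.

The generative model: each disease subtype c is an ordered sequence S_c of
N = 3*B events, where event (b, l) marks biomarker b reaching integer
z-score level l (1, 2 or 3).  A subject at stage k of subtype c has expected
z-scores given by piecewise-linear interpolation of each biomarker's
trajectory through its three event positions, observed with independent
Gaussian noise (SD sigma_b per biomarker).  Stages carry a uniform prior on
the grid 0..N; subtypes mix with fractions f_c.

Fitting maximises the data log-likelihood by greedy relocation hill-climbing
over sequences inside an EM loop over subtype responsibilities, initialised
hierarchically by splitting the clusters of the (C-1)-subtype solution.  The
number of subtypes is chosen by the cross-validation information criterion
(CVIC): the sum over folds of -2 x held-out log-likelihood, minimised over C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import logsumexp
from scipy.stats import kendalltau

from .panel import BiomarkerPanel, Z_LEVELS

MAX_SUBTYPES = 5

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Event sequences
# ---------------------------------------------------------------------------

class EventSequence:
    """Ordered tuple of (biomarker index, z-level) events.

    Valid sequences contain each (biomarker, level) pair exactly once, with
    level 1 before level 2 before level 3 for every biomarker.
    """

    __slots__ = ("events", "_positions")

    def __init__(self, events, n_biomarkers: int | None = None):
        events = tuple((int(b), int(l)) for b, l in events)
        if n_biomarkers is None:
            n_biomarkers = max(b for b, _ in events) + 1 if events else 0
        expected = {(b, l) for b in range(n_biomarkers) for l in Z_LEVELS}
        if set(events) != expected or len(events) != len(expected):
            raise ValueError("sequence must contain each (biomarker, level) exactly once")
        pos = np.empty((n_biomarkers, len(Z_LEVELS)), dtype=np.int64)
        for p, (b, l) in enumerate(events, start=1):
            pos[b, l - 1] = p
        if not (np.diff(pos, axis=1) > 0).all():
            raise ValueError("levels of each biomarker must appear in increasing order")
        self.events = events
        self._positions = pos

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventSequence) and self.events == other.events

    def __hash__(self) -> int:
        return hash(self.events)

    def __repr__(self) -> str:
        return f"EventSequence({list(self.events)!r})"

    @property
    def n_biomarkers(self) -> int:
        return self._positions.shape[0]

    def positions(self) -> np.ndarray:
        """1-based event positions, shape (B, 3): positions()[b, l-1]."""
        return self._positions.copy()


def random_sequence(n_biomarkers: int, rng: np.random.Generator) -> EventSequence:
    """Uniform random valid sequence: independent event times sorted within biomarker."""
    times = np.sort(rng.random((n_biomarkers, len(Z_LEVELS))), axis=1)
    order = np.argsort(times, axis=None, kind="stable")
    events = [(int(i // len(Z_LEVELS)), int(i % len(Z_LEVELS)) + 1) for i in order]
    return EventSequence(events, n_biomarkers)


def sequence_from_positions(pos: np.ndarray) -> EventSequence:
    """Inverse of :meth:`EventSequence.positions`."""
    pos = np.asarray(pos)
    n_b = pos.shape[0]
    order = np.argsort(pos, axis=None, kind="stable")
    events = [(int(i // 3), int(i % 3) + 1) for i in order]
    return EventSequence(events, n_b)


def sequence_kendall_tau(a: EventSequence, b: EventSequence) -> float:
    """Kendall rank correlation between the event orderings of two sequences."""
    return float(kendalltau(a.positions().ravel(), b.positions().ravel()).statistic)


# ---------------------------------------------------------------------------
# Expected trajectories and likelihoods
# ---------------------------------------------------------------------------

def _expected_matrix_from_knots(knots: np.ndarray, n_events: int) -> np.ndarray:
    """Expected z for stages 0..N given 1-based knot positions.

    ``knots`` has shape (..., B, 3); returns (..., N+1, B).  Trajectories rise
    linearly through (0,0),(p1,1),(p2,2),(p3,3) and plateau at z = 3.
    """
    k = np.arange(n_events + 1, dtype=float)
    p = knots.astype(float)
    kk = k.reshape((1,) * (p.ndim - 2) + (-1, 1))
    p1 = p[..., None, :, 0]
    p2 = p[..., None, :, 1]
    p3 = p[..., None, :, 2]
    e = (
        np.clip(kk / p1, 0.0, 1.0)
        + np.clip((kk - p1) / (p2 - p1), 0.0, 1.0)
        + np.clip((kk - p2) / (p3 - p2), 0.0, 1.0)
    )
    return e


def expected_zscore_matrix(seq: EventSequence) -> np.ndarray:
    """Expected z-score at every (stage, biomarker), shape (N+1, B)."""
    return _expected_matrix_from_knots(seq.positions(), len(seq))


def expected_zscore(seq: EventSequence, stage: int, biomarker: int) -> float:
    """Model-expected z of ``biomarker`` at integer ``stage`` (0..N)."""
    n = len(seq)
    if not 0 <= stage <= n:
        raise ValueError(f"stage must lie in [0, {n}]")
    if not 0 <= biomarker < seq.n_biomarkers:
        raise KeyError(f"biomarker index {biomarker} not in panel")
    return float(expected_zscore_matrix(seq)[stage, biomarker])


def _as_sigma(sigma, n_biomarkers: int) -> np.ndarray:
    s = np.broadcast_to(np.asarray(sigma, dtype=float), (n_biomarkers,)).copy()
    if (s <= 0).any():
        raise ValueError("sigma must be positive")
    return s


def _stage_loglik(Z: np.ndarray, E: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Per-subject, per-stage Gaussian log-likelihood, shape (n, N+1).

    Expanded as a matmul: ||(z-e)/s||^2 = ||z/s||^2 - 2 (z/s).(e/s) + ||e/s||^2.
    """
    Zs = Z / sigma
    Es = E / sigma
    const = -0.5 * (Zs ** 2).sum(axis=1) - 0.5 * Z.shape[1] * _LOG_2PI - np.log(sigma).sum()
    return Zs @ Es.T - 0.5 * (Es ** 2).sum(axis=1)[None, :] + const[:, None]


def stage_likelihoods(z: np.ndarray, seq: EventSequence, sigma=1.0):
    """Stage posterior (uniform prior over 0..N) and log marginal for one subject.

    Returns ``(posterior, log_marginal)`` where ``posterior`` has length N+1
    and sums to one, and ``log_marginal`` is log mean_k p(z | stage k).
    """
    z = np.asarray(z, dtype=float).reshape(1, -1)
    sig = _as_sigma(sigma, seq.n_biomarkers)
    ll = _stage_loglik(z, expected_zscore_matrix(seq), sig)[0]
    log_marg = float(logsumexp(ll) - np.log(len(seq) + 1))
    post = np.exp(ll - logsumexp(ll))
    return post, log_marg


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class SustainModel:
    """Fitted multi-subtype progression model."""

    sequences: list[EventSequence]
    fractions: np.ndarray
    sigma: np.ndarray
    panel: BiomarkerPanel | None = None
    log_likelihood: float = float("nan")
    position_uncertainty: list[np.ndarray] | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.sequences) > MAX_SUBTYPES:
            raise ValueError(f"at most {MAX_SUBTYPES} subtypes are supported")
        if len(self.fractions) != len(self.sequences):
            raise ValueError("one mixture fraction per subtype required")
        if (self.fractions < 0).any() or not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("fractions must be non-negative and sum to 1")
        self.sigma = _as_sigma(self.sigma, self.sequences[0].n_biomarkers)

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    @property
    def n_stages(self) -> int:
        return len(self.sequences[0])

    def to_dict(self) -> dict:
        d = {
            "sequences": [[list(ev) for ev in s.events] for s in self.sequences],
            "fractions": self.fractions.tolist(),
            "sigma": self.sigma.tolist(),
            "log_likelihood": self.log_likelihood,
        }
        if self.panel is not None:
            d["panel"] = self.panel.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SustainModel":
        panel = BiomarkerPanel.from_dict(d["panel"]) if "panel" in d else None
        n_b = len(panel.names) if panel else None
        seqs = [EventSequence([tuple(ev) for ev in s], n_b) for s in d["sequences"]]
        return cls(
            sequences=seqs,
            fractions=np.asarray(d["fractions"]),
            sigma=np.asarray(d["sigma"]),
            panel=panel,
            log_likelihood=d.get("log_likelihood", float("nan")),
        )

    @classmethod
    def from_json(cls, path) -> "SustainModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _subject_log_marginals(Z: np.ndarray, model: SustainModel) -> np.ndarray:
    """log mean_k p(z_i | S_c, stage k) for every subject and subtype, (n, C)."""
    n_stage = model.n_stages
    out = np.empty((Z.shape[0], model.n_subtypes))
    for c, seq in enumerate(model.sequences):
        ll = _stage_loglik(Z, expected_zscore_matrix(seq), model.sigma)
        out[:, c] = logsumexp(ll, axis=1) - np.log(n_stage + 1)
    return out


def data_log_likelihood(Z: np.ndarray, model: SustainModel) -> float:
    """Total log-likelihood: sum_i log sum_c f_c * stage-marginal_c(z_i)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] == 0:
        raise ValueError("empty data")
    marg = _subject_log_marginals(Z, model)
    with np.errstate(divide="ignore"):
        logf = np.log(model.fractions)
    return float(logsumexp(marg + logf[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# Sequence optimisation (greedy relocation hill-climbing)
# ---------------------------------------------------------------------------

@dataclass
class SustainConfig:
    """Tunable fitting knobs; every random draw flows from the caller's rng/seed."""

    n_restarts: int = 25          # greedy restarts for de-novo sequence fits
    n_splits: int = 3             # random bipartitions tried per cluster when adding a subtype
    worst_fit_split_fractions: tuple[float, ...] = (0.10, 0.25)
    max_em_iter: int = 50
    em_tol: float = 1e-3          # absolute log-likelihood change stopping rule
    max_sweeps: int = 50          # relocation sweeps per greedy run
    split_restarts: int = 3       # greedy restarts for the half-cluster warm-start fits
    mcmc_iterations: int = 0      # >0 enables the positional-uncertainty sampler
    mcmc_thinning: int = 10

    def to_dict(self) -> dict:
        return asdict(self)


def _candidate_objectives(Zs: np.ndarray, Es: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted candidate objectives sum_i w_i * log stage-marginal(z_i | seq_m).

    Zs (n, B) and Es (m, N+1, B) are already scaled by 1/sigma; returns (m,)
    of sum_i w_i logsumexp_k [ Zs.Es - ||Es||^2/2 ], dropping terms constant
    across candidate sequences (subject quadratic, 2*pi, stage-prior).
    """
    m, nk, nb = Es.shape
    ll = Zs @ Es.reshape(m * nk, nb).T          # (n, m*(N+1))
    ll = ll.reshape(Zs.shape[0], m, nk)
    ll -= 0.5 * (Es ** 2).sum(axis=2)[None, :, :]
    mx = ll.max(axis=2)                          # contiguous reduction
    np.exp(ll - mx[:, :, None], out=ll)
    lse = mx + np.log(ll.sum(axis=2))            # (n, m)
    return w @ lse


def _greedy_optimize(Z, weights, sigma, seq, rng, max_sweeps) -> tuple[EventSequence, float]:
    """Best-position relocation of single events until a full sweep makes no move.

    Maximises sum_i w_i * log stage-marginal(z_i | seq).  Returns the optimised
    sequence and its weighted objective (up to subject-constant terms).
    """
    n_b = seq.n_biomarkers
    n_events = len(seq)
    # float32 is ample for comparing candidate relocations; exact
    # log-likelihoods are always recomputed in float64 by the callers.
    Zs = (np.asarray(Z, dtype=float) / sigma).astype(np.float32)
    w = np.asarray(weights, dtype=np.float32)
    sigma32 = sigma.astype(np.float32)
    events = list(seq.events)

    def objective_of(pos_matrix):
        Es = _expected_matrix_from_knots(pos_matrix, n_events).astype(np.float32) / sigma32
        return _candidate_objectives(Zs, Es, w)

    pos = seq.positions()
    current_obj = float(objective_of(pos[None])[0])

    for _ in range(max_sweeps):
        moved = False
        for ev in rng.permutation(n_events):
            b, l = events[ev]
            cur_p = events.index((b, l)) + 1
            removed = events[: cur_p - 1] + events[cur_p:]
            # valid insertion slots: after (b, l-1) and before (b, l+1) in `removed`
            lo = 1
            hi = n_events
            for q, (b2, l2) in enumerate(removed, start=1):
                if b2 == b and l2 == l - 1:
                    lo = q + 1
                if b2 == b and l2 == l + 1:
                    hi = q
                    break
            slots = np.arange(lo, hi + 1)
            # positions of remaining events for each candidate slot
            rem_rank = np.arange(1, n_events)                       # ranks in `removed`
            P = rem_rank[None, :] + (rem_rank[None, :] >= slots[:, None])
            knots = np.empty((len(slots), n_b, 3), dtype=float)
            for j, (b2, l2) in enumerate(removed):
                knots[:, b2, l2 - 1] = P[:, j]
            knots[:, b, l - 1] = slots
            objs = objective_of(knots)                              # (m,)
            best = int(np.argmax(objs))
            thr = 1e-6 * (1.0 + abs(current_obj))   # above float32 round-off
            if objs[best] > current_obj + thr and slots[best] != cur_p:
                events = removed[: slots[best] - 1] + [(b, l)] + removed[slots[best] - 1:]
                current_obj = float(objs[best])
                moved = True
        if not moved:
            break
    return EventSequence(events, n_b), current_obj


def fit_single_subtype(
    Z: np.ndarray,
    config: SustainConfig | None = None,
    sigma=1.0,
    seed: int | np.random.Generator = 0,
    weights=None,
    init: EventSequence | None = None,
) -> EventSequence:
    """Maximum-likelihood single sequence by multi-start greedy relocation."""
    config = config or SustainConfig()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] < 2:
        raise ValueError("at least 2 subjects required")
    n_b = Z.shape[1]
    sig = _as_sigma(sigma, n_b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.ones(Z.shape[0]) if weights is None else np.asarray(weights, dtype=float)

    best_seq, best_obj = None, -np.inf
    starts = max(1, config.n_restarts)
    for r in range(starts):
        if r == 0 and init is not None:
            start = init
        else:
            start = random_sequence(n_b, rng)
        seq, obj = _greedy_optimize(Z, w, sig, start, rng, config.max_sweeps)
        if obj > best_obj + 1e-10:
            best_seq, best_obj = seq, obj
    return best_seq


# ---------------------------------------------------------------------------
# Multi-subtype fitting (hierarchical split + EM)
# ---------------------------------------------------------------------------

def _responsibilities(Z, model) -> tuple[np.ndarray, float]:
    marg = _subject_log_marginals(Z, model)
    with np.errstate(divide="ignore"):
        joint = marg + np.log(model.fractions)[None, :]
    tot = logsumexp(joint, axis=1)
    return np.exp(joint - tot[:, None]), float(tot.sum())


def _em_refine(Z, sequences, fractions, sigma, config, rng) -> SustainModel:
    """Alternate responsibility updates with weighted sequence re-optimisation."""
    model = SustainModel(sequences=list(sequences), fractions=fractions, sigma=sigma)
    prev_ll = -np.inf
    for _ in range(config.max_em_iter):
        resp, ll = _responsibilities(Z, model)
        if ll < prev_ll + config.em_tol:
            break
        prev_ll = ll
        new_seqs = []
        for c in range(model.n_subtypes):
            seq, _ = _greedy_optimize(Z, resp[:, c], model.sigma,
                                      model.sequences[c], rng, config.max_sweeps)
            new_seqs.append(seq)
        fr = resp.mean(axis=0)
        fr = fr / fr.sum()
        model = SustainModel(sequences=new_seqs, fractions=fr, sigma=model.sigma)
    _, ll = _responsibilities(Z, model)
    model.log_likelihood = ll
    return model


def _hierarchy_models(Z, n_subtypes, config, sig, rng, panel=None):
    """Yield the fitted 1-, 2-, ..., C-subtype models of the hierarchical scheme."""
    seq1 = fit_single_subtype(Z, config, sig, rng)
    model = SustainModel(sequences=[seq1], fractions=[1.0], sigma=sig, panel=panel)
    model.log_likelihood = data_log_likelihood(Z, model)
    yield model

    half_cfg = SustainConfig(**{**config.to_dict(), "n_restarts": config.split_restarts})
    for c_target in range(2, n_subtypes + 1):
        resp, _ = _responsibilities(Z, model)
        hard = resp.argmax(axis=1)
        marg = _subject_log_marginals(Z, model)
        best = None
        for c_split in range(model.n_subtypes):
            members = np.flatnonzero(hard == c_split)
            if len(members) < 4:
                continue
            # candidate bipartitions: random halves, plus splits separating the
            # members the current model explains worst (the likeliest carriers
            # of an unmodelled, possibly rare, progression pattern)
            splits = []
            for _ in range(max(1, config.n_splits)):
                perm = rng.permutation(members)
                splits.append((perm[: len(perm) // 2], perm[len(perm) // 2:]))
            order = members[np.argsort(marg[members, c_split])]
            for frac in config.worst_fit_split_fractions:
                n_worst = max(2, int(len(members) * frac))
                splits.append((order[:n_worst], order[n_worst:]))
            for half_a, half_b in splits:
                try:
                    seq_a = fit_single_subtype(Z[half_a], half_cfg, sig, rng,
                                               init=model.sequences[c_split])
                    seq_b = fit_single_subtype(Z[half_b], half_cfg, sig, rng,
                                               init=model.sequences[c_split])
                except ValueError:
                    continue
                seqs = [s for j, s in enumerate(model.sequences) if j != c_split]
                seqs += [seq_a, seq_b]
                fr = np.delete(model.fractions, c_split)
                fr = np.append(fr, [model.fractions[c_split] / 2] * 2)
                cand = _em_refine(Z, seqs, fr / fr.sum(), sig, config, rng)
                if best is None or cand.log_likelihood > best.log_likelihood + 1e-10:
                    best = cand
        if best is None:
            raise ValueError(f"could not split any cluster to reach {c_target} subtypes")
        model = best
        model.panel = panel
        yield model


def fit_sustain(
    Z: np.ndarray,
    n_subtypes: int,
    config: SustainConfig | None = None,
    sigma=1.0,
    seed: int | np.random.Generator = 0,
    panel: BiomarkerPanel | None = None,
) -> SustainModel:
    """Fit a C-subtype model hierarchically: split the best (C-1)-model's clusters."""
    config = config or SustainConfig()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if not 1 <= n_subtypes <= MAX_SUBTYPES:
        raise ValueError(f"n_subtypes must lie in [1, {MAX_SUBTYPES}]")
    if Z.shape[0] < n_subtypes:
        raise ValueError("fewer subjects than subtypes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = _as_sigma(sigma, Z.shape[1])

    for model in _hierarchy_models(Z, n_subtypes, config, sig, rng, panel):
        pass
    if config.mcmc_iterations > 0:
        model.position_uncertainty = positional_uncertainty(
            Z, model, config.mcmc_iterations, config.mcmc_thinning, rng
        )
    return model


def positional_uncertainty(Z, model, n_iter=10_000, thinning=10,
                           seed: int | np.random.Generator = 0) -> list[np.ndarray]:
    """Metropolis sampler over single-event relocations, for display only.

    Returns, per subtype, a (B, 3, N) matrix of posterior probabilities that
    event (b, l) sits at each 1-based sequence position.  Point estimates are
    never taken from these samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n_events = model.n_stages
    n_b = model.sequences[0].n_biomarkers
    counts = [np.zeros((n_b, 3, n_events)) for _ in model.sequences]
    current = SustainModel([EventSequence(s.events, n_b) for s in model.sequences],
                           model.fractions.copy(), model.sigma)
    cur_ll = data_log_likelihood(Z, current)
    n_kept = 0
    for it in range(n_iter):
        c = int(rng.integers(len(current.sequences)))
        events = list(current.sequences[c].events)
        ev = int(rng.integers(n_events))
        b, l = events[ev]
        removed = events[:ev] + events[ev + 1:]
        lo, hi = 1, n_events
        for q, (b2, l2) in enumerate(removed, start=1):
            if b2 == b and l2 == l - 1:
                lo = q + 1
            if b2 == b and l2 == l + 1:
                hi = q
                break
        slot = int(rng.integers(lo, hi + 1))
        prop_events = removed[: slot - 1] + [(b, l)] + removed[slot - 1:]
        prop_seqs = list(current.sequences)
        prop_seqs[c] = EventSequence(prop_events, n_b)
        prop = SustainModel(prop_seqs, current.fractions, current.sigma)
        prop_ll = data_log_likelihood(Z, prop)
        if np.log(rng.random()) < prop_ll - cur_ll:
            current, cur_ll = prop, prop_ll
        if (it + 1) % thinning == 0:
            n_kept += 1
            for ci, s in enumerate(current.sequences):
                pos = s.positions()
                for bb in range(n_b):
                    for ll_ in range(3):
                        counts[ci][bb, ll_, pos[bb, ll_] - 1] += 1
    return [c / max(n_kept, 1) for c in counts]


# ---------------------------------------------------------------------------
# Model selection (CVIC)
# ---------------------------------------------------------------------------

def cvic_select(
    Z: np.ndarray,
    max_subtypes: int = MAX_SUBTYPES,
    folds: int = 10,
    config: SustainConfig | None = None,
    sigma=1.0,
    seed: int = 0,
    stratify_labels=None,
    parsimony: str = "min",
) -> tuple[dict[int, float], int]:
    """Per-C CVIC scores (sum over folds of -2 x held-out log-likelihood) and selected C.

    The selected C minimises the summed score.  When sequence orderings are
    weakly identified, a larger mixture can hedge ordering uncertainty and
    shave a sliver off the held-out score even without a true extra subtype;
    ``parsimony="1se"`` then selects the smallest C whose score sits within
    one standard error of the minimum (SE from paired per-fold differences).
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if max_subtypes > MAX_SUBTYPES:
        raise ValueError(f"max_subtypes cannot exceed {MAX_SUBTYPES}")
    if folds < 2:
        raise ValueError("at least 2 folds required")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] < folds * 2:
        raise ValueError("too few subjects for the requested number of folds")
    config = config or SustainConfig()

    if stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(Z, np.asarray(stratify_labels)))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(Z))

    sig = _as_sigma(sigma, Z.shape[1])
    fold_scores = np.zeros((max_subtypes, len(split_iter)))
    for i_fold, (tr, te) in enumerate(split_iter):
        rng = np.random.default_rng([seed, i_fold])
        # one hierarchical pass per fold scores every C on the held-out part
        for c, model in enumerate(_hierarchy_models(Z[tr], max_subtypes, config, sig, rng)):
            fold_scores[c, i_fold] = -2.0 * data_log_likelihood(Z[te], model)
    totals = fold_scores.sum(axis=1)
    best = int(np.argmin(totals))
    selected = best + 1
    if parsimony == "1se":
        for c in range(best):
            d = fold_scores[c] - fold_scores[best]
            se = d.std(ddof=1) * np.sqrt(len(d)) if len(d) > 1 else 0.0
            if d.sum() <= se:
                selected = c + 1
                break
    scores = {c + 1: float(totals[c]) for c in range(max_subtypes)}
    return scores, selected


# ---------------------------------------------------------------------------
# Subject assignment
# ---------------------------------------------------------------------------

@dataclass
class Assignment:
    """Per-subject maximum-likelihood subtype and stage.

    ``subtype`` is None when the ML stage is 0 or N: those stages are shared
    by every subtype, so the subtype is not identifiable there.
    """

    subtype: int | None
    stage: int
    posterior: np.ndarray  # (C, N+1), sums to 1

    @property
    def defined(self) -> bool:
        return self.subtype is not None


def assign(model: SustainModel, z: np.ndarray, weight_by_fractions: bool = True) -> Assignment:
    """Assign one subject: ML subtype (fraction-weighted by default), then ML stage."""
    z = np.asarray(z, dtype=float).reshape(1, -1)
    n_stage = model.n_stages
    ll = np.stack(
        [_stage_loglik(z, expected_zscore_matrix(s), model.sigma)[0] for s in model.sequences]
    )  # (C, N+1)
    with np.errstate(divide="ignore"):
        logf = np.log(model.fractions) if weight_by_fractions else np.zeros(model.n_subtypes)
    joint = ll - np.log(n_stage + 1) + logf[:, None]
    posterior = np.exp(joint - logsumexp(joint))
    marg_per_subtype = logsumexp(joint, axis=1)
    subtype = int(np.argmax(marg_per_subtype))        # ties -> lower index
    stage = int(np.argmax(joint[subtype]))            # ties -> lower stage
    if stage in (0, n_stage):
        return Assignment(subtype=None, stage=stage, posterior=posterior)
    return Assignment(subtype=subtype, stage=stage, posterior=posterior)


def assign_cohort(model: SustainModel, Z: np.ndarray,
                  weight_by_fractions: bool = True) -> list[Assignment]:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return [assign(model, z, weight_by_fractions) for z in Z]
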