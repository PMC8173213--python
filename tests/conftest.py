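import itertools

import numpy as np
import pytest

from sustainval import BiomarkerPanel, EventSequence


@pytest.fixture(scope="session")
def panel2():
    return BiomarkerPanel(("A", "B"))


@pytest.fixture(scope="session")
def seq2():
    """The interleaved 2-biomarker toy sequence used in the hand examples."""
    return EventSequence([(0, 1), (1, 1), (0, 2), (1, 2), (0, 3), (1, 3)], 2)


def all_valid_sequences(n_biomarkers: int):
    """Enumerate every valid event ordering (oracle; 20 sequences for B=2)."""
    events = [(b, l) for b in range(n_biomarkers) for l in (1, 2, 3)]
    out = []
    for perm in itertools.permutations(events):
        ok = True
        for b in range(n_biomarkers):
            levels = [l for bb, l in perm if bb == b]
            if levels != [1, 2, 3]:
                ok = False
                break
        if ok:
            out.append(EventSequence(perm, n_biomarkers))
    return out


@pytest.fixture(scope="session")
def all_sequences_b2():
    seqs = all_valid_sequences(2)
    assert len(seqs) == 20  # 6!/(3!*3!)
    return seqs


def brute_stage_posterior(z, seq, sigma=1.0):
    """Independent double-loop likelihood oracle (stages x biomarkers)."""
    from scipy.stats import norm
    from sustainval import expected_zscore

    z = np.asarray(z, dtype=float)
    n = len(seq)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), z.shape)
    lik = np.empty(n + 1)
    for k in range(n + 1):
        p = 1.0
        for b in range(len(z)):
            p *= norm.pdf(z[b], loc=expected_zscore(seq, k, b), scale=sig[b])
        lik[k] = p
    marginal = lik.mean()
    return lik / lik.sum(), marginal


def brute_data_log_likelihood(Z, sequences, fractions, sigma=1.0):
    """Triple-loop mixture log-likelihood oracle (subjects x subtypes x stages)."""
    total = 0.0
    for z in np.atleast_2d(Z):
        mix = 0.0
        for seq, f in zip(sequences, fractions):
            _, marg = brute_stage_posterior(z, seq, sigma)
            mix += f * marg
        total += np.log(mix)
    return total
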