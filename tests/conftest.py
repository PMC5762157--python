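import numpy as np
import pytest

import songeval as se


@pytest.fixture(scope="session")
def repertoire():
    return se.make_tutor_repertoire(3, seed=1)


@pytest.fixture(scope="session")
def session(repertoire):
    """A mid-stage session with enough renditions for the 40-rendition rules."""
    return se.make_session(stage=0.5, n_syllables=150, repertoire=repertoire, seed=11)


@pytest.fixture(scope="session")
def session_spike_context(session):
    """Episodes, annotations and baselines for the shared session."""
    from songeval import spikes as sk
    from songeval.synth import singing_annotations

    episodes = sk.segment_episodes(session.segments)
    annotations = singing_annotations(session)
    baselines = sk.find_baselines(annotations, (0.0, session.total_duration))
    return episodes, annotations, baselines


def dtw_brute_force(a: np.ndarray, b: np.ndarray, penalty: float) -> float:
    """Exhaustive enumeration of all monotone alignment paths (oracle).

    Independent of the DP implementation: generates every path from (0,0)
    to (n-1,m-1) with steps (1,1), (1,0), (0,1), sums the frame costs along
    the path plus a penalty per non-diagonal step, and returns the minimum.
    Only feasible for tracks of <= ~7 frames.
    """
    a = np.atleast_2d(np.asarray(a, float).T).T
    b = np.atleast_2d(np.asarray(b, float).T).T
    n, m = a.shape[0], b.shape[0]
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    suffix_cache: dict[tuple[int, int], list[list[tuple[int, int]]]] = {}

    def suffixes(i, j):
        if (i, j) in suffix_cache:
            return suffix_cache[(i, j)]
        if i == n - 1 and j == m - 1:
            out = [[(i, j)]]
        else:
            out = []
            for di, dj in ((1, 1), (1, 0), (0, 1)):
                ni, nj = i + di, j + dj
                if ni < n and nj < m:
                    for p in suffixes(ni, nj):
                        out.append([(i, j)] + p)
        suffix_cache[(i, j)] = out
        return out

    best = np.inf
    for path in suffixes(0, 0):
        c = sum(cost[i, j] for i, j in path)
        non_diag = sum(
            1
            for (i0, j0), (i1, j1) in zip(path, path[1:])
            if (i1 - i0) + (j1 - j0) != 2
        )
        best = min(best, c + penalty * non_diag)
    return float(best)
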