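import itertools

import numpy as np
import pytest
from hypothesis import settings

from isopick.elements import DELTA_M
from isopick.peaks import IsotopeCluster, Peak
from isopick.quantiles import build_quantile_tables, compound_ratios
from isopick.simulate import simulate_formula_db, reference_cluster_table, reference_spectrum
from isopick.workflow import load_default_tables

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: printed minimal detection errors (Da, ppm) per reference substance
REFERENCE_ERRORS = {
    "aspartic acid": (0.00191, 14.3),
    "cysteine": (0.00895, 73.9),
    "chloramphenicol": (0.00913, 28.4),
    "digoxigenin monodigitoxoside": (0.00078, 1.5),
    "2-chloro-2'-deoxyadenosine-5'-triphosphate": (0.00817, 15.6),
    "autoinducer-2": (0.00689, 35.9),
}


@pytest.fixture(scope="session")
def reference_table():
    return reference_cluster_table()


@pytest.fixture(scope="session")
def reference_peaks():
    return reference_spectrum()


@pytest.fixture(scope="session")
def default_tables():
    return load_default_tables()


@pytest.fixture(scope="session")
def small_db_records():
    """Ratio records for a small synthetic formula database."""
    formulas = simulate_formula_db(400, (60.0, 900.0), seed=11)
    return compound_ratios(formulas)


@pytest.fixture(scope="session")
def small_tables(small_db_records):
    return build_quantile_tables(small_db_records, window_size=50.0,
                                 source_name="small")


def make_peaks(mzs, intensities=None, rt=100.0, sn=np.inf):
    if intensities is None:
        intensities = [1000.0] * len(mzs)
    return [
        Peak(id=f"p{k}", mz=float(m), rt=rt, intensity=float(a), sn=sn)
        for k, (m, a) in enumerate(zip(mzs, intensities))
    ]


# ---------------------------------------------------------------------------
# Independent brute-force detection oracle: enumerate every increasing
# subsequence of the peak list for every charge and keep the best valid
# chain under the documented ordering, iterating with removal.

def _chain_valid(mzs, idx, spacing, tol):
    return all(
        abs((mzs[b] - mzs[a]) - spacing) <= tol
        for a, b in zip(idx, idx[1:])
    )


def _chain_key(mzs, intensities, idx, spacing, z):
    steps = tuple(
        (abs(mzs[b] - mzs[a] - spacing), -intensities[b])
        for a, b in zip(idx, idx[1:])
    )
    return (-len(idx), mzs[idx[0]], z, steps)


def oracle_clusters(peaks, Z=3, ppm_tol=0.0, abs_tol=0.01):
    """Exhaustive-enumeration counterpart of find_putative_clusters."""
    peaks = sorted(peaks, key=lambda p: p.mz)
    alive = list(range(len(peaks)))
    clusters = []
    while len(alive) >= 2:
        mzs = {i: peaks[i].mz for i in alive}
        intens = {i: peaks[i].intensity for i in alive}
        candidates = []
        for z in range(1, Z + 1):
            spacing = DELTA_M / z
            for size in range(2, len(alive) + 1):
                for idx in itertools.combinations(alive, size):
                    tol = max(mzs[idx[0]] * ppm_tol / 1e6, abs_tol)
                    if _chain_valid(mzs, idx, spacing, tol):
                        candidates.append(
                            (_chain_key(mzs, intens, idx, spacing, z), idx, z)
                        )
        if not candidates:
            break
        key, idx, z = min(candidates)
        clusters.append(
            IsotopeCluster(peaks=[peaks[i] for i in idx], charge=z)
        )
        alive = [i for i in alive if i not in idx]
    clusters.sort(key=lambda c: c.mono.mz)
    return clusters


def cluster_signature(clusters):
    return sorted(
        (c.charge, tuple(round(p.mz, 6) for p in c.peaks)) for c in clusters
    )
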