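"""Shared fixtures and independent oracles for the test suite.

The expansion oracle below recomputes, with plain numpy operations on
the raw fixture matrix, the rows an IGD file must contain — a code path
fully independent of the writer's expansion logic.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from igdkit import Fixture, make_matrix

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def oracle_rows(fx: Fixture) -> list[tuple]:
    """Expected (position, alt_number, num_copies, is_missing, samples)
    rows for a fixture, recounted directly from the ground-truth matrix.

    alt_number is 1-based; 0 marks the IS_MISSING row.  For unphased
    data an individual with any missing call counts as missing and
    contributes to no copy row.
    """
    rows = []
    for s, site in enumerate(fx.sites):
        k = len(site.alt_alleles)
        cell = fx.matrix[s]
        if fx.phased:
            flat = cell.reshape(-1)
            for j in range(k):
                rows.append(
                    (site.position, j + 1, 0, False,
                     np.flatnonzero(flat == j + 1).tolist())
                )
            miss = np.flatnonzero(flat == -1).tolist()
        else:
            ind_missing = (cell == -1).any(axis=1)
            for j in range(k):
                counts = (cell == j + 1).sum(axis=1)
                counts[ind_missing] = 0
                present = sorted(set(counts[counts > 0].tolist()))
                if not present:
                    rows.append((site.position, j + 1, 1, False, []))
                for c in present:
                    rows.append(
                        (site.position, j + 1, c, False,
                         np.flatnonzero(counts == c).tolist())
                    )
            miss = np.flatnonzero(ind_missing).tolist()
        if miss:
            rows.append((site.position, 0, 0 if fx.phased else 1, True, miss))
    return rows


FAMILY = [
    # (name, kwargs) — covers phased/unphased, ploidy 1-3, multiallelic,
    # missing present/absent, and both frequency regimes
    ("phased-diploid", dict(num_individuals=20, ploidy=2, phased=True)),
    ("unphased-diploid", dict(num_individuals=20, ploidy=2, phased=False)),
    ("phased-haploid", dict(num_individuals=15, ploidy=1, phased=True)),
    ("unphased-haploid", dict(num_individuals=15, ploidy=1, phased=False)),
    ("phased-triploid-missing",
     dict(num_individuals=12, ploidy=3, phased=True, missing_rate=0.1)),
    ("unphased-triploid-missing",
     dict(num_individuals=12, ploidy=3, phased=False, missing_rate=0.1)),
    ("phased-diploid-missing",
     dict(num_individuals=25, ploidy=2, phased=True, missing_rate=0.1)),
    ("unphased-diploid-missing",
     dict(num_individuals=25, ploidy=2, phased=False, missing_rate=0.1)),
    ("rare-spectrum",
     dict(num_individuals=50, ploidy=2, phased=True, spectrum="rare")),
    ("common-spectrum",
     dict(num_individuals=16, ploidy=2, phased=True, spectrum="common")),
    ("tiny", dict(num_individuals=1, ploidy=2, phased=True, num_sites=5)),
]


@pytest.fixture(params=FAMILY, ids=[name for name, _ in FAMILY])
def family_fixture(request) -> Fixture:
    name, kwargs = request.param
    return make_matrix(seed=7, num_sites=kwargs.pop("num_sites", 20), **kwargs)


@pytest.fixture
def write_fixture(tmp_path):
    """Write a Fixture to an IGD file in tmp_path; returns (path, report)."""
    from igdkit import write_igd

    def _write(fx: Fixture, name: str = "fx.igd", **kwargs):
        path = tmp_path / name
        report = write_igd(
            path,
            fx.sites,
            num_individuals=fx.num_individuals,
            ploidy=fx.ploidy,
            phased=fx.phased,
            individual_ids=fx.individual_ids,
            **kwargs,
        )
        return path, report

    return _write
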