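"""Deterministic synthetic genotype datasets for exercising the format.

The generator produces small hard-call genotype matrices with a
controllable allele-frequency spectrum, multiallelic sites, missing
calls, and any ploidy, together with the matching VCF text.  The ground
truth matrix is materialized before any encoding happens, so round-trip
tests compare against data the codec never touched.

The default frequency spectrum is a discretized neutral-like 1/x
spectrum (P(carrier count = c) proportional to 1/c), mimicking the
rare-variant-rich composition of large sequencing cohorts at toy scale.
Two extreme spectra are provided to force all-sparse ("rare", every
variant below the 1/32 sparsity break-even) and all-dense ("common")
files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .writer import MISSING, SiteInput

Spectrum = Literal["neutral", "rare", "common"]


@dataclass
class Fixture:
    """A synthetic dataset plus its ground truth.

    ``matrix`` has shape (num_sites, N, ploidy) holding call values
    0..k or -1 for missing — the pre-encoding source of truth for all
    oracle checks.
    """

    sites: list[SiteInput]
    matrix: np.ndarray
    positions: list[int]
    phased: bool
    ploidy: int
    num_individuals: int
    individual_ids: list[str]
    contig: str = "chr1"

    @property
    def num_sites(self) -> int:
        return len(self.sites)

    def alt_allele_count(self, site: int, alt: int) -> int:
        """Hard-call count of alternate allele ``alt`` (1-based) at a site,
        recounted from the raw matrix."""
        return int((self.matrix[site] == alt).sum())

    def missing_sample_count(self, site: int) -> int:
        """Haploid slots (phased) or individuals (unphased) lacking a call."""
        miss = self.matrix[site] == MISSING
        return int(miss.sum()) if self.phased else int(miss.any(axis=1).sum())


def _draw_carrier_count(rng: np.random.Generator, nh: int, spectrum: Spectrum) -> int:
    if nh <= 1:
        return 1 if nh == 1 else 0
    if spectrum == "neutral":
        counts = np.arange(1, nh)
        p = 1.0 / counts
        return int(rng.choice(counts, p=p / p.sum()))
    if spectrum == "rare":
        # strictly below the 1/32 break-even whenever nh > 32
        cap = max(1, nh // 64)
        return int(rng.integers(1, cap + 1))
    if spectrum == "common":
        lo = max(1, nh // 3)
        return int(rng.integers(lo, nh // 2 + 1))
    raise ValueError(f"unknown spectrum {spectrum!r}")


def make_matrix(
    seed: int,
    num_individuals: int = 30,
    ploidy: int = 2,
    num_sites: int = 25,
    *,
    phased: bool = True,
    alt_count_probs: Sequence[float] = (0.85, 0.09, 0.04, 0.02),
    spectrum: Spectrum = "neutral",
    missing_rate: float = 0.0,
    with_ids: bool = True,
) -> Fixture:
    """Generate a reproducible genotype dataset.

    ``alt_count_probs[j]`` is the probability a site has j+1 alternate
    alleles.  ``missing_rate`` is applied per haploid slot for phased
    data and per individual for unphased data (an unphased genotype is
    either fully called or fully missing, matching what per-copy-count
    storage can represent losslessly).  Positions are strictly
    increasing.  The same seed always yields the same fixture.
    """
    rng = np.random.default_rng(seed)
    nh = num_individuals * ploidy
    positions = (1 + np.cumsum(rng.integers(1, 50, size=num_sites))).tolist()
    alt_k = rng.choice(
        np.arange(1, len(alt_count_probs) + 1),
        size=num_sites,
        p=np.asarray(alt_count_probs) / np.sum(alt_count_probs),
    )
    bases = ["A", "C", "G", "T"]

    matrix = np.zeros((num_sites, num_individuals, ploidy), dtype=np.int16)
    sites: list[SiteInput] = []
    for s in range(num_sites):
        k = int(alt_k[s])
        ref = bases[int(rng.integers(4))]
        alts = [b for b in bases if b != ref][:k]
        if k > 3:  # more alts than single bases: use short indels
            alts = alts + [ref + "T" * j for j in range(1, k - 2)]
        flat = matrix[s].reshape(-1)
        perm = rng.permutation(nh)
        used = 0
        for j in range(k):
            c = min(_draw_carrier_count(rng, nh, spectrum), nh - used)
            flat[perm[used : used + c]] = j + 1
            used += c
        if missing_rate > 0:
            if phased:
                mask = rng.random(nh) < missing_rate
                flat[mask] = MISSING
            else:
                mask = rng.random(num_individuals) < missing_rate
                matrix[s][mask, :] = MISSING
        sites.append(
            SiteInput(
                position=int(positions[s]),
                ref=ref,
                alt_alleles=alts,
                genotypes=[tuple(int(c) for c in g) for g in matrix[s]],
                variant_ids=[f"site{s}"] * k if with_ids else None,
            )
        )

    ids = [f"ind{n:04d}" for n in range(num_individuals)]
    return Fixture(
        sites=sites,
        matrix=matrix,
        positions=positions,
        phased=phased,
        ploidy=ploidy,
        num_individuals=num_individuals,
        individual_ids=ids,
    )


def make_vcf(fixture: Fixture) -> str:
    """Render a fixture as VCF 4.2 text equivalent to its matrix.

    Phased genotypes use the ``|`` separator and preserve slot order;
    unphased genotypes use ``/`` with alleles listed in ascending order
    (only the copy counts are meaningful).  Missing calls are ``.``.
    """
    sep = "|" if fixture.phased else "/"
    out = io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    out.write(f"##contig=<ID={fixture.contig}>\n")
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(fixture.individual_ids)
        + "\n"
    )
    for s, site in enumerate(fixture.sites):
        vid = site.variant_ids[0] if site.variant_ids else "."
        row = [
            fixture.contig,
            str(site.position),
            vid,
            site.ref,
            ",".join(site.alt_alleles),
            ".",
            ".",
            ".",
            "GT",
        ]
        for geno in fixture.matrix[s]:
            calls = [int(c) for c in geno]
            if not fixture.phased:
                calls.sort()  # unphased order is arbitrary; canonicalize
            row.append(sep.join("." if c == MISSING else str(c) for c in calls))
        out.write("\t".join(row) + "\n")
    return out.getvalue()
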