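"""Diploid microsatellite genotype container and CSV I/O.

Genotypes are stored as an ``(n_individuals, n_loci, 2)`` integer array of
allele labels, with ``-1`` marking a missing allele.  An individual is
*typed* at a locus only if both alleles are present; single-allele records
are treated as untyped (and counted as such in summaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: strings accepted as a missing allele in CSV input
_NA_STRINGS = {"", "?", "??", "na", "nan", "none"}


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with a missing-data mask."""

    individuals: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n, L, 2) int, MISSING = -1

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L = len(self.individuals), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n} individuals x {L} loci"
            )
        if len(set(self.individuals)) != n:
            raise ValueError("individual ids must be unique")
        # a half-called genotype is demoted to fully missing
        half = (self.alleles == MISSING).any(axis=2)
        self.alleles[half] = MISSING

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): individual fully typed at locus."""
        return (self.alleles != MISSING).all(axis=2)

    def drop_loci(self, names: list[str]) -> "GenotypeTable":
        keep = [i for i, l in enumerate(self.loci) if l not in set(names)]
        return GenotypeTable(
            list(self.individuals),
            [self.loci[i] for i in keep],
            self.alleles[:, keep, :].copy(),
        )

    def subset(self, ids: list[str]) -> "GenotypeTable":
        index = {ind: i for i, ind in enumerate(self.individuals)}
        rows = [index[i] for i in ids]
        return GenotypeTable(list(ids), list(self.loci), self.alleles[rows].copy())

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_col: str = "id") -> "GenotypeTable":
        """Build from a wide table with ``<locus>_a`` / ``<locus>_b`` columns."""
        loci = []
        for c in df.columns:
            if c.endswith("_a") and c[:-2] + "_b" in df.columns:
                loci.append(c[:-2])
        if not loci:
            raise ValueError("no '<locus>_a'/'<locus>_b' column pairs found")
        n = len(df)
        alleles = np.full((n, len(loci), 2), MISSING, dtype=int)

        def parse(v) -> int:
            if pd.isna(v) or str(v).strip().lower() in _NA_STRINGS:
                return MISSING
            return int(float(v))

        for j, locus in enumerate(loci):
            alleles[:, j, 0] = [parse(v) for v in df[locus + "_a"]]
            alleles[:, j, 1] = [parse(v) for v in df[locus + "_b"]]
        return cls([str(i) for i in df[id_col]], loci, alleles)

    @classmethod
    def from_csv(cls, path, id_col: str = "id") -> "GenotypeTable":
        return cls.from_dataframe(pd.read_csv(path, comment="#"), id_col=id_col)

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, object] = {"id": self.individuals}
        for j, locus in enumerate(self.loci):
            a = self.alleles[:, j, 0].astype(object)
            b = self.alleles[:, j, 1].astype(object)
            a[a == MISSING] = ""
            b[b == MISSING] = ""
            data[locus + "_a"] = a
            data[locus + "_b"] = b
        return pd.DataFrame(data)

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_dataframe().to_csv(fh, index=False)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele -> frequency maps estimated from typed individuals."""

    loci: list[str]
    frequencies: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus in self.loci:
            freqs = self.frequencies[locus]
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {total}, not 1")

    def __getitem__(self, locus: str) -> dict[int, float]:
        return self.frequencies[locus]

    def n_alleles(self, locus: str) -> int:
        return len(self.frequencies[locus])

    def as_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per locus: (allele labels, frequencies) as aligned arrays."""
        out = {}
        for locus in self.loci:
            items = sorted(self.frequencies[locus].items())
            out[locus] = (
                np.array([a for a, _ in items], dtype=int),
                np.array([f for _, f in items], dtype=float),
            )
        return out


def allele_frequencies(genotypes: GenotypeTable) -> AlleleFrequencyTable:
    """Sample allele frequencies: allele count / total allele count among
    fully typed individuals at each locus.

    Raises ``ValueError`` naming the locus if no individual is typed there.
    """
    typed = genotypes.typed_mask()
    freqs: dict[str, dict[int, float]] = {}
    for j, locus in enumerate(genotypes.loci):
        rows = typed[:, j]
        if not rows.any():
            raise ValueError(f"locus {locus!r} has no typed individuals")
        alleles = genotypes.alleles[rows, j, :].ravel()
        labels, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): float(c) / total for a, c in zip(labels, counts)}
    return AlleleFrequencyTable(list(genotypes.loci), freqs)
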