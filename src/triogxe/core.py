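"""Domain types and elementary genetics for case-parent trio data.

A trio is an affected child plus both genotyped parents. Genotypes at the
(biallelic) test locus are coded 0/1/2 as counts of the index ("1") allele.
Haplotypes at the causal/test locus pair are labelled R1, R0, N1, N0, where
R/N are the risk and non-risk alleles at the unmeasured causal locus and
1/0 the alleles at the measured test locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

HAPLOTYPES = ("R1", "R0", "N1", "N0")

GENOTYPES = (0, 1, 2)


class MendelError(ValueError):
    """A child genotype incompatible with its parents' genotypes."""


class MonomorphicLocusError(ValueError):
    """Allelic correlation requested at a locus fixed in the stratum."""


def _transmission_probs(g: int) -> np.ndarray:
    """P(transmit index allele) for a parent with genotype g."""
    return np.array([1.0 - g / 2.0, g / 2.0])


def _build_mendel_table() -> np.ndarray:
    table = np.zeros((3, 3, 3))
    for gm in GENOTYPES:
        for gf in GENOTYPES:
            tm = _transmission_probs(gm)
            tf = _transmission_probs(gf)
            for am in (0, 1):
                for af in (0, 1):
                    table[gm, gf, am + af] += tm[am] * tf[af]
    return table


_MENDEL = _build_mendel_table()


def mendelian_probs(g_mother: int, g_father: int) -> np.ndarray:
    """Distribution of the child's genotype given parental genotypes.

    Each parent transmits one of its two alleles with equal probability;
    the child's genotype is the number of index alleles received.

    Returns a length-3 probability vector over child genotypes {0, 1, 2}.
    Symmetric in the parents.
    """
    if g_mother not in GENOTYPES or g_father not in GENOTYPES:
        raise ValueError(
            f"genotypes must be in {{0,1,2}}, got ({g_mother!r}, {g_father!r})"
        )
    return _MENDEL[g_mother, g_father].copy()


def is_informative(g_mother: int, g_father: int) -> bool:
    """True iff at least one parent is heterozygous at the test locus.

    Only such trios carry information in the conditional likelihood: with
    both parents homozygous the child's genotype is fully determined.
    """
    if g_mother not in GENOTYPES or g_father not in GENOTYPES:
        raise ValueError(
            f"genotypes must be in {{0,1,2}}, got ({g_mother!r}, {g_father!r})"
        )
    return g_mother == 1 or g_father == 1


@dataclass(frozen=True)
class HaplotypeTable:
    """Per-stratum frequencies of the four causal/test-locus haplotypes.

    ``freq[s]`` is the probability vector over (R1, R0, N1, N0) in stratum
    ``strata[s]``. Each row must be a probability vector.
    """

    strata: tuple[int, ...]
    freq: np.ndarray

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape != (len(self.strata), 4):
            raise ValueError(
                f"freq must have shape ({len(self.strata)}, 4), got {freq.shape}"
            )
        if np.any(freq < 0):
            raise ValueError("haplotype frequencies must be nonnegative")
        if np.any(np.abs(freq.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("each stratum's haplotype frequencies must sum to 1")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "strata", tuple(int(s) for s in self.strata))

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    def _index(self, stratum: int) -> int:
        try:
            return self.strata.index(stratum)
        except ValueError:
            raise KeyError(f"stratum {stratum} not in table (has {self.strata})")

    def frequencies(self, stratum: int) -> np.ndarray:
        """Haplotype frequency vector (R1, R0, N1, N0) for one stratum."""
        return self.freq[self._index(stratum)].copy()

    def p_risk(self, stratum: int) -> float:
        """Marginal frequency of the causal risk allele R."""
        f = self.freq[self._index(stratum)]
        return float(f[0] + f[1])

    def p_index(self, stratum: int) -> float:
        """Marginal frequency of the test-locus index allele 1."""
        f = self.freq[self._index(stratum)]
        return float(f[0] + f[2])

    def subset(self, strata: Sequence[int]) -> "HaplotypeTable":
        idx = [self._index(s) for s in strata]
        return HaplotypeTable(tuple(strata), self.freq[idx])


def default_haplotype_table() -> HaplotypeTable:
    """The four-stratum haplotype configuration used throughout the simulations.

    Strata 0 and 1 put the two loci in complete (opposite-sign) linkage
    disequilibrium; strata 2 and 3 have intermediate LD. The implied allelic
    correlations between R and 1 are (-1, 1, 0.5, -0.5).
    """
    freq = np.array(
        [
            # R1    R0     N1     N0
            [0.000, 0.500, 0.500, 0.000],  # S = 0
            [0.500, 0.000, 0.000, 0.500],  # S = 1
            [0.375, 0.125, 0.125, 0.375],  # S = 2
            [0.125, 0.375, 0.375, 0.125],  # S = 3
        ]
    )
    return HaplotypeTable((0, 1, 2, 3), freq)


def allelic_correlation(table: HaplotypeTable, stratum: int) -> float:
    """Correlation between the R and 1 allele indicators on a haplotype.

    r = (f(R1) - p_R p_1) / sqrt(p_R (1-p_R) p_1 (1-p_1)), the usual
    haplotype-level LD correlation. Undefined (raises) when either locus is
    monomorphic in the stratum.
    """
    f = table.frequencies(stratum)
    p_r = f[0] + f[1]
    p_1 = f[0] + f[2]
    denom = p_r * (1.0 - p_r) * p_1 * (1.0 - p_1)
    if denom <= 0.0:
        raise MonomorphicLocusError(
            f"allelic correlation undefined in stratum {stratum}: "
            f"p_R={p_r:.3g}, p_1={p_1:.3g}"
        )
    return float((f[0] - p_r * p_1) / np.sqrt(denom))


@dataclass
class TrioRecord:
    """One case-parent trio: child/parent test-locus genotypes, exposure,
    adjustment covariates and (optionally) the oracle stratum label."""

    g_child: int
    g_mother: int
    g_father: int
    exposure: float
    covariates: np.ndarray = field(default_factory=lambda: np.zeros(0))
    stratum: int | None = None

    def __post_init__(self) -> None:
        for g in (self.g_child, self.g_mother, self.g_father):
            if g not in GENOTYPES:
                raise ValueError(f"genotype {g!r} not in {{0,1,2}}")
        if mendelian_probs(self.g_mother, self.g_father)[self.g_child] == 0.0:
            raise MendelError(
                f"child genotype {self.g_child} impossible for parents "
                f"({self.g_mother}, {self.g_father})"
            )
        self.covariates = np.atleast_1d(np.asarray(self.covariates, dtype=float))

    @property
    def informative(self) -> bool:
        return is_informative(self.g_mother, self.g_father)


@dataclass
class TrioDataset:
    """Column-oriented container for a set of case-parent trios.

    ``covariates`` is the n-by-K adjustment matrix X (K may be 0);
    ``stratum`` carries oracle labels when the data come from the simulator.
    """

    g_child: np.ndarray
    g_mother: np.ndarray
    g_father: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray | None = None
    stratum: np.ndarray | None = None
    exposure_type: str = "continuous"

    def __post_init__(self) -> None:
        self.g_child = np.asarray(self.g_child, dtype=np.int64)
        self.g_mother = np.asarray(self.g_mother, dtype=np.int64)
        self.g_father = np.asarray(self.g_father, dtype=np.int64)
        self.exposure = np.asarray(self.exposure, dtype=float)
        n = self.g_child.shape[0]
        if self.covariates is None:
            self.covariates = np.zeros((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum, dtype=np.int64)
        for name in ("g_mother", "g_father", "exposure"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"column {name} has wrong length")
        if self.covariates.shape[0] != n:
            raise ValueError("covariates have wrong number of rows")
        if self.exposure_type not in ("continuous", "binary"):
            raise ValueError(f"unknown exposure_type {self.exposure_type!r}")
        for g in (self.g_child, self.g_mother, self.g_father):
            if n and (g.min() < 0 or g.max() > 2):
                raise ValueError("genotypes must be in {0,1,2}")
        bad = np.flatnonzero(
            _MENDEL[self.g_mother, self.g_father, self.g_child] == 0.0
        )
        if bad.size:
            raise MendelError(
                f"Mendel-incompatible trios at rows {bad.tolist()[:20]}"
                + ("..." if bad.size > 20 else "")
            )

    @classmethod
    def from_records(
        cls, records: Sequence[TrioRecord], exposure_type: str = "continuous"
    ) -> "TrioDataset":
        if not records:
            return cls(
                np.zeros(0, int), np.zeros(0, int), np.zeros(0, int),
                np.zeros(0), exposure_type=exposure_type,
            )
        k = records[0].covariates.shape[0]
        if any(r.covariates.shape[0] != k for r in records):
            raise ValueError("all records must have the same covariate length")
        strata = None
        if all(r.stratum is not None for r in records):
            strata = np.array([r.stratum for r in records])
        return cls(
            g_child=np.array([r.g_child for r in records]),
            g_mother=np.array([r.g_mother for r in records]),
            g_father=np.array([r.g_father for r in records]),
            exposure=np.array([r.exposure for r in records]),
            covariates=np.array([r.covariates for r in records]).reshape(len(records), k),
            stratum=strata,
            exposure_type=exposure_type,
        )

    def __len__(self) -> int:
        return int(self.g_child.shape[0])

    @property
    def n_trios(self) -> int:
        return len(self)

    @property
    def k_covariates(self) -> int:
        return int(self.covariates.shape[1])

    @property
    def informative(self) -> np.ndarray:
        """Boolean mask: at least one heterozygous parent."""
        return (self.g_mother == 1) | (self.g_father == 1)

    def __getitem__(self, i: int) -> TrioRecord:
        return TrioRecord(
            int(self.g_child[i]), int(self.g_mother[i]), int(self.g_father[i]),
            float(self.exposure[i]), self.covariates[i].copy(),
            None if self.stratum is None else int(self.stratum[i]),
        )

    def records(self) -> Iterator[TrioRecord]:
        for i in range(len(self)):
            yield self[i]

    def with_covariates(self, x: np.ndarray) -> "TrioDataset":
        """Copy of the dataset with the adjustment matrix replaced."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[0] != len(self):
            raise ValueError("covariate rows must match the number of trios")
        return TrioDataset(
            self.g_child, self.g_mother, self.g_father, self.exposure,
            covariates=x, stratum=self.stratum, exposure_type=self.exposure_type,
        )


_REQUIRED_COLUMNS = ("child", "mother", "father", "exposure")


def _covariate_columns(columns: Sequence[str]) -> list[str]:
    cols = [c for c in columns if c.startswith("x") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def read_trios(path, exposure_type: str = "continuous") -> TrioDataset:
    """Read a delimited trio file (tab or comma, auto-detected).

    Required columns: child, mother, father, exposure. Optional: stratum and
    covariate columns x1..xK. Lines starting with '#' are comments.
    Mendel-incompatible rows raise :class:`MendelError` naming the rows.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trio file {path} missing required columns {missing}")
    for col in ("child", "mother", "father"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.all(np.isin(vals.dropna(), (0, 1, 2))):
            bad = df.index[~vals.isin((0, 1, 2))].tolist()[:20]
            raise ValueError(f"unparsable genotypes in column {col!r} at rows {bad}")
        df[col] = vals.astype(int)
    stratum = df["stratum"].to_numpy(int) if "stratum" in df.columns else None
    xcols = _covariate_columns(df.columns)
    covariates = df[xcols].to_numpy(float) if xcols else None
    return TrioDataset(
        g_child=df["child"].to_numpy(),
        g_mother=df["mother"].to_numpy(),
        g_father=df["father"].to_numpy(),
        exposure=df["exposure"].to_numpy(float),
        covariates=covariates,
        stratum=stratum,
        exposure_type=exposure_type,
    )


def write_trios(path, data: TrioDataset, sep: str = "\t", header_comment: str | None = None) -> None:
    """Write a dataset in the trio-file schema; integer genotypes round-trip exactly."""
    cols: dict[str, np.ndarray] = {
        "child": data.g_child,
        "mother": data.g_mother,
        "father": data.g_father,
        "exposure": data.exposure,
    }
    if data.stratum is not None:
        cols["stratum"] = data.stratum
    for k in range(data.k_covariates):
        cols[f"x{k + 1}"] = data.covariates[:, k]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)
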