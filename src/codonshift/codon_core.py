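"""Genetic-code bookkeeping and the codon-choice probability model.

The model: for an amino acid with ``n_aa`` synonymous codons, the probability
of codon *i* in gene *g* is

    p_i = exp(-dM_i - deta_i * phi_g) / sum_j exp(-dM_j - deta_j * phi_g)

where ``dM`` is the log mutation-rate ratio and ``deta`` the selection
coefficient (in s*Ne units at phi = 1), both relative to a per-family
reference codon, and ``phi_g`` is the gene's evolutionary-average protein
production rate (scaled so the genome mean is 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "STOP_CODONS",
    "SINGLE_CODON_AMINO_ACIDS",
    "CodonFamily",
    "CodonFamilyTable",
    "ParameterSet",
    "ExpressionVector",
    "CodonCountMatrix",
    "codon_probabilities",
    "family_probabilities",
    "loglikelihood",
    "expected_frequency_curve",
    "count_codons",
]

_STANDARD = _BioCodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
#: Amino acids with a single codon; excluded from the model entirely.
SINGLE_CODON_AMINO_ACIDS = frozenset({"M", "W"})

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodonFamily:
    """One synonymous-codon family (an amino acid, or a serine half-family)."""

    family_id: str
    codons: tuple[str, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if self.n_aa < 2:
            raise ValueError(
                f"family {self.family_id!r} has {self.n_aa} codon(s); need >= 2"
            )
        if not 0 <= self.reference_index < self.n_aa:
            raise ValueError(
                f"family {self.family_id!r}: reference_index out of range"
            )
        aas = {_STANDARD.forward_table[c] for c in self.codons}
        if len(aas) != 1:
            raise ValueError(
                f"family {self.family_id!r} mixes amino acids: {sorted(aas)}"
            )

    @property
    def n_aa(self) -> int:
        return len(self.codons)

    @property
    def reference_codon(self) -> str:
        return self.codons[self.reference_index]


def _standard_families(serine_split: bool) -> tuple[CodonFamily, ...]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in _STANDARD.forward_table.items():
        if set(codon) <= _VALID_BASES:
            by_aa.setdefault(aa, []).append(codon)
    families: list[CodonFamily] = []
    for aa, codons in by_aa.items():
        if aa in SINGLE_CODON_AMINO_ACIDS:
            continue
        if aa == "S" and serine_split:
            tcn = sorted(c for c in codons if c.startswith("TC"))
            agn = sorted(c for c in codons if c.startswith("AG"))
            families.append(CodonFamily("S4", tuple(tcn)))
            families.append(CodonFamily("S2", tuple(agn)))
        else:
            families.append(CodonFamily(aa, tuple(sorted(codons))))
    families.sort(key=lambda f: f.family_id)
    return tuple(families)


@dataclass(frozen=True)
class CodonFamilyTable:
    """Synonymous-codon families of the standard genetic code.

    With the serine split (TCN vs AGC/AGT) there are 19 families covering the
    59 sense codons of multi-codon amino acids, one reference codon each, so
    40 free parameters per parameter class.
    """

    families: tuple[CodonFamily, ...]
    serine_split: bool = True

    @classmethod
    def standard(cls, serine_split: bool = True) -> "CodonFamilyTable":
        return cls(_standard_families(serine_split), serine_split)

    @property
    def codons(self) -> tuple[str, ...]:
        """All modeled codons, in family order then within-family order."""
        return tuple(c for f in self.families for c in f.codons)

    @property
    def n_codons(self) -> int:
        return sum(f.n_aa for f in self.families)

    @property
    def n_free_parameters(self) -> int:
        """Free parameters per class (non-reference codons)."""
        return sum(f.n_aa - 1 for f in self.families)

    def codon_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.codons)}

    def family_slices(self) -> dict[str, slice]:
        """Slice of each family in the flat codon ordering."""
        out: dict[str, slice] = {}
        start = 0
        for f in self.families:
            out[f.family_id] = slice(start, start + f.n_aa)
            start += f.n_aa
        return out

    def family_of(self) -> dict[str, str]:
        return {c: f.family_id for f in self.families for c in f.codons}

    def family(self, family_id: str) -> CodonFamily:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)


@dataclass
class ParameterSet:
    """Per-codon mutation bias (delta_M) and selection (delta_eta).

    Values are relative to each family's reference codon, which is held at
    exactly zero.  Arrays are aligned with ``table.codons``.
    """

    table: CodonFamilyTable
    delta_M: np.ndarray
    delta_eta: np.ndarray

    def __post_init__(self) -> None:
        self.delta_M = np.asarray(self.delta_M, dtype=float)
        self.delta_eta = np.asarray(self.delta_eta, dtype=float)
        n = self.table.n_codons
        if self.delta_M.shape != (n,) or self.delta_eta.shape != (n,):
            raise ValueError(f"parameter arrays must have shape ({n},)")
        if not (np.isfinite(self.delta_M).all() and np.isfinite(self.delta_eta).all()):
            raise ValueError("parameters must be finite")
        for fam, sl in zip(self.table.families, self.table.family_slices().values()):
            ref = sl.start + fam.reference_index
            if self.delta_M[ref] != 0.0 or self.delta_eta[ref] != 0.0:
                raise ValueError(
                    f"reference codon {fam.reference_codon} of family "
                    f"{fam.family_id} must have delta_M = delta_eta = 0"
                )

    @classmethod
    def zeros(cls, table: CodonFamilyTable) -> "ParameterSet":
        n = table.n_codons
        return cls(table, np.zeros(n), np.zeros(n))

    @classmethod
    def from_values(
        cls,
        table: CodonFamilyTable,
        delta_M: Mapping[str, float],
        delta_eta: Mapping[str, float],
    ) -> "ParameterSet":
        idx = table.codon_index()
        dm = np.zeros(table.n_codons)
        de = np.zeros(table.n_codons)
        for codon, v in delta_M.items():
            dm[idx[codon]] = v
        for codon, v in delta_eta.items():
            de[idx[codon]] = v
        return cls(table, dm, de)

    def family_values(self, family_id: str) -> tuple[np.ndarray, np.ndarray]:
        sl = self.table.family_slices()[family_id]
        return self.delta_M[sl], self.delta_eta[sl]

    def to_frame(self) -> pd.DataFrame:
        fam_of = self.table.family_of()
        codons = self.table.codons
        return pd.DataFrame(
            {
                "family_id": [fam_of[c] for c in codons],
                "codon": list(codons),
                "delta_M": self.delta_M,
                "delta_eta": self.delta_eta,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, table: CodonFamilyTable | None = None) -> "ParameterSet":
        df = pd.read_csv(path)
        table = table or CodonFamilyTable.standard()
        return cls.from_values(
            table,
            dict(zip(df["codon"], df["delta_M"])),
            dict(zip(df["codon"], df["delta_eta"])),
        )


@dataclass
class ExpressionVector:
    """Per-gene protein production rates phi, scaled so the mean is 1."""

    gene_ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if len(self.gene_ids) != self.phi.shape[0]:
            raise ValueError("gene_ids and phi length mismatch")
        if not (self.phi > 0).all():
            raise ValueError("all phi must be positive")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "phi": self.phi})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ExpressionVector":
        df = pd.read_csv(path)
        return cls(list(df["gene_id"].astype(str)), df["phi"].to_numpy())


@dataclass
class CodonCountMatrix:
    """Gene x codon counts (sufficient statistics for the likelihood)."""

    table: CodonFamilyTable
    gene_ids: list[str]
    counts: np.ndarray  # shape (n_genes, table.n_codons), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), self.table.n_codons):
            raise ValueError("counts shape does not match gene_ids/table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def total(self) -> int:
        return int(self.counts.sum())

    def family_counts(self, family_id: str) -> np.ndarray:
        return self.counts[:, self.table.family_slices()[family_id]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.table.codons)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="gene_id")

    @classmethod
    def read_csv(cls, path, table: CodonFamilyTable | None = None) -> "CodonCountMatrix":
        table = table or CodonFamilyTable.standard()
        df = pd.read_csv(path, index_col="gene_id")
        df = df.loc[:, list(table.codons)]
        return cls(table, [str(g) for g in df.index], df.to_numpy())


def family_probabilities(delta_M, delta_eta, phi: float) -> np.ndarray:
    """Softmax of -(delta_M + delta_eta * phi) over one family's codons.

    Raw-array core of :func:`codon_probabilities`; invariant to adding any
    constant to delta_M (or to delta_eta) across the family.
    """
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    x = -(np.asarray(delta_M, dtype=float) + np.asarray(delta_eta, dtype=float) * phi)
    x = x - x.max()  # overflow safety
    ex = np.exp(x)
    return ex / ex.sum()


def codon_probabilities(
    family: CodonFamily,
    params: ParameterSet,
    phi: float,
) -> np.ndarray:
    """Probability of each codon of ``family`` in a gene with production rate ``phi``.

    At phi = 0 selection is absent and mutation bias alone sets the
    frequencies; at phi = 1 the gene has average expression.
    """
    dm, de = params.family_values(family.family_id)
    return family_probabilities(dm, de, phi)


def expected_frequency_curve(
    family: CodonFamily,
    params: ParameterSet,
    phi_grid: Sequence[float],
) -> np.ndarray:
    """Expected codon frequencies of a family across a grid of phi values.

    Returns an array of shape ``(len(phi_grid), family.n_aa)``; each row sums
    to 1 and equals :func:`codon_probabilities` at that phi.
    """
    grid = np.asarray(phi_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("phi_grid must be nonempty")
    return np.vstack([codon_probabilities(family, params, p) for p in grid])


def loglikelihood(
    counts: CodonCountMatrix,
    params: ParameterSet,
    phis: ExpressionVector,
) -> float:
    """Multinomial log-likelihood of per-gene codon counts under the model."""
    if counts.gene_ids != phis.gene_ids:
        raise ValueError("counts and phis must cover the same genes, in order")
    phi = phis.phi
    total = 0.0
    for fam, sl in counts.table.family_slices().items():
        n = counts.counts[:, sl]
        if n.sum() == 0:
            continue
        dm = params.delta_M[sl]
        de = params.delta_eta[sl]
        x = -(dm[None, :] + np.outer(phi, de))
        x -= x.max(axis=1, keepdims=True)
        logp = x - np.log(np.exp(x).sum(axis=1, keepdims=True))
        total += float((n * logp).sum())
    return total


def count_codons(
    sequence: Sequence[str],
    site_mask: Sequence[bool] | None = None,
    table: CodonFamilyTable | None = None,
    gene_id: str = "<unnamed>",
) -> np.ndarray:
    """Count modeled codons at unmasked sites of one codon sequence.

    ATG, TGG, and stop codons are ignored for model counts; a stop codon at
    an unmasked site is an error (internal stop), as is any codon containing
    a non-ACGT base.
    """
    table = table or CodonFamilyTable.standard()
    if site_mask is None:
        site_mask = [True] * len(sequence)
    if len(site_mask) != len(sequence):
        raise ValueError(f"gene {gene_id}: mask length != sequence length")
    idx = table.codon_index()
    out = np.zeros(table.n_codons, dtype=int)
    for pos, (codon, keep) in enumerate(zip(sequence, site_mask), start=1):
        if not keep:
            continue
        codon = codon.upper()
        if not set(codon) <= _VALID_BASES or len(codon) != 3:
            raise ValueError(f"gene {gene_id}: invalid codon {codon!r} at site {pos}")
        if codon in STOP_CODONS:
            raise ValueError(f"gene {gene_id}: internal stop codon at site {pos}")
        j = idx.get(codon)
        if j is not None:  # ATG / TGG silently ignored
            out[j] += 1
    return out


def count_matrix(
    genes: Mapping[str, Sequence[str]],
    masks: Mapping[str, Sequence[bool]] | None = None,
    table: CodonFamilyTable | None = None,
) -> CodonCountMatrix:
    """Build a :class:`CodonCountMatrix` from per-gene codon sequences."""
    table = table or CodonFamilyTable.standard()
    gene_ids = list(genes)
    rows = [
        count_codons(
            genes[g],
            None if masks is None else masks[g],
            table,
            gene_id=g,
        )
        for g in gene_ids
    ]
    return CodonCountMatrix(table, gene_ids, np.vstack(rows) if rows else np.zeros((0, table.n_codons), int))
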