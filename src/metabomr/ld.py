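"""Linkage-disequilibrium reference matrices.

An :class:`LDMatrix` stores signed pairwise correlations (r, not r^2) among a
set of variants together with their base-pair positions and the allele to
which the sign of r refers.  It can be loaded from a variant manifest plus a
dense matrix, or computed from a small 0/1 haplotype panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LDMatrix:
    variant_ids: list[str]
    r: np.ndarray
    positions: np.ndarray
    aligned_allele: list[str] | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.positions = np.asarray(self.positions)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("|r| must be <= 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def idx(self, variant_id: str) -> int:
        return self._index[variant_id]

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def pos(self, variant_id: str) -> int:
        return int(self.positions[self._index[variant_id]])

    def submatrix(self, variant_ids: list[str]) -> "LDMatrix":
        ix = [self._index[v] for v in variant_ids]
        allele = ([self.aligned_allele[i] for i in ix]
                  if self.aligned_allele is not None else None)
        return LDMatrix(list(variant_ids), self.r[np.ix_(ix, ix)],
                        self.positions[ix], allele)


def ld_from_genotypes(panel: pd.DataFrame, positions=None) -> LDMatrix:
    """Compute signed r from a variants x haplotypes table of 0/1 dosages.

    Row index gives variant IDs; monomorphic variants are rejected.
    """
    geno = panel.to_numpy(dtype=float)
    sd = geno.std(axis=1)
    if np.any(sd == 0):
        bad = list(panel.index[sd == 0])
        raise ValueError(f"monomorphic variants in panel: {bad}")
    r = np.corrcoef(geno)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if positions is None:
        positions = np.arange(1, len(panel) + 1)
    return LDMatrix(list(map(str, panel.index)), r, np.asarray(positions))


def read_ld(manifest_path, matrix_path, sep: str = "\t") -> LDMatrix:
    """Load an LDMatrix from a manifest (ID, CHR, BP, ALLELE) + dense matrix."""
    manifest = pd.read_csv(manifest_path, sep=sep)
    r = np.loadtxt(matrix_path)
    if r.ndim == 0:
        r = r.reshape(1, 1)
    return LDMatrix(list(manifest["ID"].astype(str)), r,
                    manifest["BP"].to_numpy(),
                    list(manifest["ALLELE"]) if "ALLELE" in manifest else None)


def write_ld(ld: LDMatrix, manifest_path, matrix_path, chrom: str = "1",
             sep: str = "\t") -> None:
    manifest = pd.DataFrame({
        "ID": ld.variant_ids, "CHR": chrom, "BP": ld.positions,
        "ALLELE": ld.aligned_allele if ld.aligned_allele is not None else "A",
    })
    manifest.to_csv(manifest_path, sep=sep, index=False)
    np.savetxt(matrix_path, ld.r, fmt="%.8g")
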