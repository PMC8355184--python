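"""Genotype dosage container with VCF round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]

_GT_FROM_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass
class GenotypeMatrix:
    """Variants x samples dosage matrix (0/1/2 alternate-allele counts).

    ``variants`` has columns variant_id, chrom, pos (0-based), ref, alt, maf.
    """

    variants: pd.DataFrame
    samples: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage shape mismatch")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> dict:
        return {v: i for i, v in enumerate(self.variants["variant_id"])}

    def empirical_maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def write_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 with GT fields (1-based positions)."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            chroms = pd.unique(self.variants["chrom"])
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            cols = "\t".join(str(s) for s in self.samples)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
            for i, row in enumerate(self.variants.itertuples(index=False)):
                gts = "\t".join(_GT_FROM_DOSAGE[int(d)] for d in self.dosages[i])
                fh.write(
                    f"{row.chrom}\t{int(row.pos) + 1}\t{row.variant_id}\t"
                    f"{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Load biallelic variants from a VCF via cyvcf2 (positions 0-based)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = np.asarray(vcf.samples, dtype=object)
        rows, dosages = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            # with gts012=True: 0/1/2 = alt-allele dosage, 3 = unknown
            dose = np.asarray(var.gt_types, dtype=np.int8)
            dose[dose == 3] = 0
            vid = var.ID or f"{var.CHROM}_{var.POS}"
            rows.append((vid, var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
            dosages.append(dose)
        variants = pd.DataFrame(
            rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
        )
        dos = np.asarray(dosages, dtype=np.int8).reshape(len(rows), len(samples))
        freq = dos.mean(axis=1) / 2.0
        variants["maf"] = np.minimum(freq, 1.0 - freq)
        return cls(variants=variants, samples=samples, dosages=dos)
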