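"""Genetic diversity statistics for SNP genotype panels.

Implements the per-marker indices routinely reported for germplasm panels —
genotype number (NG), allele number (NA), major allele frequency (MAF), gene
diversity (GD = 1 − Σp²), heterozygosity and Botstein's polymorphic
information content (PIC) — plus panel-level summaries over a marker set.

``He`` here is the *observed* heterozygosity (fraction of heterozygous
genotype calls).  Pea is a predominantly selfing crop, so observed
heterozygosity sits far below gene diversity; the unbiased expected
heterozygosity is reported separately as ``He_exp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_CALL = "./."

#: Marker-set labels: loci with neutral mutations vs loci in heat-shock
#: protein / heat-shock transcription-factor genes.
NEUTRAL = "NEUTRAL"
HT_RELATED = "HT_RELATED"

HIGH = "HIGH"
MODERATE = "MODERATE"
SLIGHT = "SLIGHT"


def _parse_call(call: str) -> tuple[str, str] | None:
    """Parse an "A/G"-style genotype string; ``None`` for a missing call."""
    if call is None or call == MISSING_CALL or call == "" or (isinstance(call, float) and np.isnan(call)):
        return None
    a, _, b = call.partition("/")
    if not b:
        raise ValueError(f"malformed genotype call {call!r}")
    if a == "." or b == ".":
        return None
    return (a, b)


class GenotypeMatrix:
    """Accessions × markers table of unordered allele-pair calls.

    Parameters
    ----------
    calls : DataFrame
        Rows indexed by accession id, columns by marker id, cells are
        ``"A/G"``-style strings or ``"./."`` for missing.
    marker_set : mapping, optional
        Marker id → ``NEUTRAL`` or ``HT_RELATED``.  Defaults to ``NEUTRAL``
        for every marker.
    """

    def __init__(self, calls: pd.DataFrame, marker_set: Mapping[str, str] | None = None):
        self.calls = calls.astype(str)
        if marker_set is None:
            marker_set = {m: NEUTRAL for m in calls.columns}
        self.marker_set = {m: marker_set.get(m, NEUTRAL) for m in calls.columns}

    # -- basic views -------------------------------------------------------
    @property
    def accession_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_accessions(self) -> int:
        return len(self.calls.index)

    @property
    def n_markers(self) -> int:
        return len(self.calls.columns)

    def markers_in_set(self, which: str | None) -> list[str]:
        if which is None:
            return self.marker_ids
        return [m for m in self.marker_ids if self.marker_set[m] == which]

    def column(self, marker: str) -> list[tuple[str, str] | None]:
        return [_parse_call(c) for c in self.calls[marker]]

    def subset(self, accessions: Sequence[str] | None = None, markers: Sequence[str] | None = None) -> "GenotypeMatrix":
        df = self.calls
        if accessions is not None:
            df = df.loc[list(accessions)]
        if markers is not None:
            df = df[list(markers)]
        return GenotypeMatrix(df, {m: self.marker_set[m] for m in df.columns})

    def encoded(self, markers: Sequence[str] | None = None) -> tuple[np.ndarray, list[list[str]]]:
        """Integer-coded genotypes for numerical work.

        Returns ``(codes, alleles)`` where ``codes`` is an
        ``(n_accessions, n_markers, 2)`` int8 array of per-marker allele
        indices (−1 = missing) and ``alleles[j]`` lists the observed alleles
        of marker *j* in sorted order.
        """
        if markers is None:
            markers = self.marker_ids
        n = self.n_accessions
        codes = np.full((n, len(markers), 2), -1, dtype=np.int8)
        alleles: list[list[str]] = []
        for j, m in enumerate(markers):
            col = self.column(m)
            obs = sorted({a for pair in col if pair is not None for a in pair})
            idx = {a: k for k, a in enumerate(obs)}
            alleles.append(obs)
            for i, pair in enumerate(col):
                if pair is not None:
                    codes[i, j, 0] = idx[pair[0]]
                    codes[i, j, 1] = idx[pair[1]]
        return codes, alleles

    # -- I/O ---------------------------------------------------------------
    def to_table(self, path: str | Path, sep: str = "\t") -> None:
        out = self.calls.copy()
        out.index.name = "accession"
        header = pd.DataFrame(
            {m: [self.marker_set[m]] for m in self.marker_ids}, index=pd.Index(["#marker_set"], name="accession")
        )
        pd.concat([header, out]).to_csv(path, sep=sep)

    @classmethod
    def from_table(cls, path: str | Path, sep: str = "\t") -> "GenotypeMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        marker_set = None
        if "#marker_set" in df.index:
            marker_set = df.loc["#marker_set"].to_dict()
            df = df.drop(index="#marker_set")
        df.index.name = None
        return cls(df, marker_set)

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal single-sample-per-column VCF (GT field only)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##INFO=<ID=SET,Number=1,Type=String,Description="Marker set">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.accession_ids) + "\n")
            for pos, m in enumerate(self.marker_ids, start=1):
                col = self.column(m)
                obs = sorted({a for pair in col if pair is not None for a in pair})
                if not obs:
                    obs = ["N"]
                ref, alts = obs[0], obs[1:]
                idx = {a: k for k, a in enumerate(obs)}
                gts = []
                for pair in col:
                    if pair is None:
                        gts.append("./.")
                    else:
                        gts.append(f"{idx[pair[0]]}/{idx[pair[1]]}")
                alt_field = ",".join(alts) if alts else "."
                fh.write(
                    f"1\t{pos}\t{m}\t{ref}\t{alt_field}\t.\t.\tSET={self.marker_set[m]}\tGT\t" + "\t".join(gts) + "\n"
                )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        samples: list[str] = []
        rows: dict[str, list[str]] = {}
        marker_set: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                if line.startswith("#CHROM"):
                    samples = line.split("\t")[9:]
                    continue
                parts = line.split("\t")
                mid, ref, alt, info = parts[2], parts[3], parts[4], parts[7]
                alleles = [ref] + ([] if alt == "." else alt.split(","))
                mset = NEUTRAL
                for kv in info.split(";"):
                    if kv.startswith("SET="):
                        mset = kv[4:]
                marker_set[mid] = mset
                calls = []
                for gt in parts[9:]:
                    gt = gt.split(":")[0]
                    if "." in gt:
                        calls.append(MISSING_CALL)
                    else:
                        i, j = (int(x) for x in gt.replace("|", "/").split("/"))
                        calls.append(f"{alleles[i]}/{alleles[j]}")
                rows[mid] = calls
        df = pd.DataFrame(rows, index=samples)
        return cls(df, marker_set)


@dataclass
class MarkerStats:
    """Diversity indices for one marker."""

    marker_id: str
    NG: int
    NA: int
    MAF: float
    GD: float
    He: float
    He_exp: float
    PIC: float
    info_class: str
    n_typed: int
    defined: bool = True


def allele_frequencies(column: Iterable[tuple[str, str] | None]) -> dict[str, float]:
    """Allele frequencies from both copies of the non-missing calls."""
    counts: dict[str, int] = {}
    for pair in column:
        if pair is None:
            continue
        for a in pair:
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all calls missing; allele frequencies undefined")
    return {a: c / total for a, c in sorted(counts.items())}


def pic_botstein(freqs: Sequence[float]) -> float:
    """Polymorphic information content, PIC = 1 − Σp² − Σ_{i<j} 2 p_i² p_j²."""
    p = np.asarray(list(freqs), dtype=float)
    s2 = float(np.sum(p**2))
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - s2 - cross


def classify_informativeness(pic: float) -> str:
    """Marker informativeness class from PIC: ≥0.5 high, [0.25,0.5) moderate, <0.25 slight."""
    if not 0.0 <= pic <= 1.0:
        raise ValueError(f"PIC out of range: {pic}")
    if pic >= 0.5:
        return HIGH
    if pic >= 0.25:
        return MODERATE
    return SLIGHT


def marker_stats(column: Iterable[tuple[str, str] | None], marker_id: str = "") -> MarkerStats:
    """Compute NG, NA, MAF, GD, He (observed), He_exp and PIC for one marker."""
    col = list(column)
    typed = [pair for pair in col if pair is not None]
    if not typed:
        return MarkerStats(marker_id, 0, 0, np.nan, np.nan, np.nan, np.nan, np.nan, SLIGHT, 0, defined=False)
    freqs = allele_frequencies(typed)
    p = np.array(list(freqs.values()))
    n = len(typed)
    genotypes = {tuple(sorted(pair)) for pair in typed}
    gd = 1.0 - float(np.sum(p**2))
    he_obs = sum(1 for a, b in typed if a != b) / n
    he_exp = gd * n / (n - 1) if n > 1 else gd
    pic = pic_botstein(p)
    return MarkerStats(
        marker_id=marker_id,
        NG=len(genotypes),
        NA=len(freqs),
        MAF=float(np.max(p)),
        GD=gd,
        He=he_obs,
        He_exp=he_exp,
        PIC=pic,
        info_class=classify_informativeness(max(0.0, pic)),
        n_typed=n,
    )


def all_marker_stats(matrix: GenotypeMatrix, marker_set: str | None = None) -> pd.DataFrame:
    """Per-marker stats table for the markers in ``marker_set`` (or all)."""
    rows = []
    for m in matrix.markers_in_set(marker_set):
        st = marker_stats(matrix.column(m), m)
        rows.append(
            {
                "marker": st.marker_id,
                "marker_set": matrix.marker_set[m],
                "NG": st.NG,
                "NA": st.NA,
                "MAF": st.MAF,
                "GD": st.GD,
                "He": st.He,
                "He_exp": st.He_exp,
                "PIC": st.PIC,
                "info_class": st.info_class,
                "n_typed": st.n_typed,
                "defined": st.defined,
            }
        )
    return pd.DataFrame(rows)


def panel_summary(matrix: GenotypeMatrix, marker_set: str | None = None) -> dict:
    """Panel totals and means over one marker set.

    Totals (NG, NA) are sums over markers; MAF/GD/He/PIC are unweighted
    marker means; counts per informativeness class are included.
    """
    table = all_marker_stats(matrix, marker_set)
    if not table.empty:
        table = table[table["defined"]]
    if table.empty:
        raise ValueError(f"no defined markers in set {marker_set!r}")
    return {
        "marker_set": marker_set if marker_set is not None else "ALL",
        "n_markers": int(len(table)),
        "total_NG": int(table["NG"].sum()),
        "total_NA": int(table["NA"].sum()),
        "mean_MAF": float(table["MAF"].mean()),
        "mean_GD": float(table["GD"].mean()),
        "mean_He": float(table["He"].mean()),
        "mean_PIC": float(table["PIC"].mean()),
        "n_high": int((table["info_class"] == HIGH).sum()),
        "n_moderate": int((table["info_class"] == MODERATE).sum()),
        "n_slight": int((table["info_class"] == SLIGHT).sum()),
    }
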