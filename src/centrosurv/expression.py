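"""Expression-matrix ingestion and centrosome-amplification gene analytics.

Works on gene x sample matrices of log2-scale expression (the layout of
normalized one-channel microarray series).  Provides a reader/writer for
the GEO Series Matrix text layout, probe-to-gene collapsing, the
KIFC1-anchored Pearson correlation panel over centrosome-amplification
(CA) driver genes, and the cumulative centrosome amplification index
(CAI): the per-sample sum of log2 expression over a small panel of
centrosome structural and CA-driver genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CA_CORRELATION_PANEL",
    "CAI_PANELS",
    "SeriesMatrixError",
    "read_series_matrix",
    "write_series_matrix",
    "read_expression_csv",
    "collapse_probes",
    "correlation_panel",
    "cai",
    "CAITable",
]

# Genes whose dysregulation drives centrosome amplification, used as the
# correlation panel against the KIFC1 anchor.
CA_CORRELATION_PANEL = [
    "CCNA2", "CDK1", "NEK2", "AURKA", "MYCN", "CCNE2", "STIL", "LMO4",
    "PLK4", "MDM2", "CEP63", "E2F1", "E2F2", "E2F3", "CEP152", "PIM1",
    "PIN1", "CCND1",
]

# Two shipped CAI presets: a 5-gene panel (structural proteins centrin-2,
# gamma-tubulin, pericentrin plus drivers PLK4 and cyclin E) and a 7-gene
# variant that adds the Aurora kinases.  Both are configurable.
CAI_PANELS = {
    "results": ["CETN2", "TUBG1", "PCNT2", "PLK4", "CCNE1"],
    "methods": ["PLK4", "AURKA", "AURKB", "CCNE1", "CETN2", "TUBG1", "PCNT"],
}

# Default mapping from !Sample_characteristics_ch1 keys to clinical columns.
DEFAULT_CHARACTERISTIC_KEYS = {
    "histotype": "histotype",
    "site": "site",
    "grade": "grade",
    "stage": "stage",
    "os_months": "os_months",
    "event": "event",
}

_MISSING_TOKENS = {"", "null", "na", "nan", "NA", "NaN", "NULL", "None"}


class SeriesMatrixError(ValueError):
    """Malformed GEO Series Matrix file (message carries the line number)."""


def _parse_cell(token: str, line_no: int):
    token = token.strip().strip('"')
    if token in _MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError as exc:
        raise SeriesMatrixError(
            f"line {line_no}: non-numeric expression value {token!r}"
        ) from exc


def read_series_matrix(path, characteristic_keys=None, scale_tag: str = "log2"):
    """Parse a GEO Series-Matrix-style text file.

    The layout: "!"-prefixed key/value header lines (tab separated), a
    numeric table bracketed by ``!series_matrix_table_begin`` /
    ``!series_matrix_table_end`` whose first column holds probe/gene ids
    and whose header row holds sample ids.  Sample characteristics lines
    (``!Sample_characteristics_ch1``) of the form ``key: value`` are
    mapped to clinical columns via ``characteristic_keys``.

    With ``scale_tag="linear"`` the matrix is log2-transformed on read.

    Returns ``(matrix, clinical)``: a genes x samples DataFrame (attrs
    carry ``scale_tag``) and a clinical DataFrame (one row per sample;
    empty if the file carries no characteristics).
    """
    if scale_tag not in ("log2", "linear"):
        raise ValueError("scale_tag must be 'log2' or 'linear'")
    keymap = dict(DEFAULT_CHARACTERISTIC_KEYS)
    keymap.update(characteristic_keys or {})

    char_rows: list[list[str]] = []
    table_lines: list[tuple[int, str]] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            low = line.lower()
            if low.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if low.startswith("!series_matrix_table_end"):
                in_table = False
                saw_end = True
                continue
            if in_table:
                table_lines.append((line_no, line))
            elif line.startswith("!Sample_characteristics"):
                char_rows.append(line.split("\t")[1:])
    if not saw_begin or not saw_end:
        raise SeriesMatrixError(
            "missing !series_matrix_table_begin/!series_matrix_table_end markers"
        )
    if not table_lines:
        raise SeriesMatrixError("empty expression table")

    hdr_no, header = table_lines[0]
    cols = [c.strip().strip('"') for c in header.split("\t")]
    sample_ids = cols[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise SeriesMatrixError(
            f"line {hdr_no}: duplicate sample columns {dupes}"
        )
    gene_ids, rows = [], []
    for line_no, line in table_lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise SeriesMatrixError(
                f"line {line_no}: ragged row ({len(parts)} fields, "
                f"expected {len(cols)})"
            )
        gene_ids.append(parts[0].strip().strip('"'))
        rows.append([_parse_cell(v, line_no) for v in parts[1:]])
    matrix = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    if scale_tag == "linear":
        with np.errstate(divide="ignore"):
            matrix = np.log2(matrix)
        matrix.attrs["scale_tag"] = "log2"
        matrix.attrs["provenance"] = "log2-transformed from linear input"
    else:
        matrix.attrs["scale_tag"] = "log2"

    clinical = pd.DataFrame({"sample_id": sample_ids})
    for row in char_rows:
        for j, cell in enumerate(row[: len(sample_ids)]):
            cell = cell.strip().strip('"')
            if ":" not in cell:
                continue
            key, _, value = cell.partition(":")
            key = key.strip()
            if key in keymap:
                clinical.loc[j, keymap[key]] = value.strip()
    for col in ("os_months", "event", "grade"):
        if col in clinical.columns:
            clinical[col] = pd.to_numeric(clinical[col], errors="coerce")
    return matrix, clinical


def write_series_matrix(path, matrix: pd.DataFrame,
                        clinical: pd.DataFrame | None = None) -> None:
    """Write a genes x samples matrix (plus optional per-sample
    characteristics) in the Series Matrix text layout read by
    :func:`read_series_matrix`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!Series_title\t\"synthetic cohort\"\n")
        if clinical is not None:
            clin = clinical.set_index("sample_id").loc[list(matrix.columns)]
            for col in clin.columns:
                cells = "\t".join(
                    f"\"{col}: {clin[col].iloc[j]}\"" for j in range(len(clin))
                )
                fh.write(f"!Sample_characteristics_ch1\t{cells}\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write("\"ID_REF\"\t" + "\t".join(f"\"{s}\"" for s in matrix.columns) + "\n")
        for gene, row in matrix.iterrows():
            vals = "\t".join("null" if np.isnan(v) else repr(float(v))
                             for v in row.to_numpy())
            fh.write(f"\"{gene}\"\t{vals}\n")
        fh.write("!series_matrix_table_end\n")


def read_expression_csv(path, scale_tag: str = "log2") -> pd.DataFrame:
    """Read a genes x samples CSV (first column gene ids, header sample ids)."""
    matrix = pd.read_csv(path, index_col=0)
    matrix.index = matrix.index.astype(str)
    if scale_tag == "linear":
        matrix = np.log2(matrix)
    matrix.attrs["scale_tag"] = "log2"
    return matrix


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict,
                    method: str = "max_mean") -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene symbol.

    ``max_mean`` keeps, for each gene, the probe with the highest mean
    across samples; ``first`` keeps the first probe in matrix order.
    Probes absent from the mapping are dropped.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    if method not in ("max_mean", "first"):
        raise ValueError("method must be 'max_mean' or 'first'")
    keep_rows: dict[str, str] = {}
    for probe in matrix.index:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in keep_rows:
            keep_rows[gene] = probe
        elif method == "max_mean":
            if matrix.loc[probe].mean() > matrix.loc[keep_rows[gene]].mean():
                keep_rows[gene] = probe
    if not keep_rows:
        raise ValueError("no probe in the matrix maps to a gene symbol")
    out = matrix.loc[list(keep_rows.values())].copy()
    out.index = list(keep_rows.keys())
    out.attrs.update(matrix.attrs)
    return out


def correlation_panel(matrix: pd.DataFrame, anchor_gene: str = "KIFC1",
                      panel=None) -> pd.DataFrame:
    """Pearson correlation of each panel gene with the anchor gene.

    Pairwise-complete observations; two-sided p from the t distribution
    with n-2 df; rows sorted by descending r.  Raw p-values are the
    primary significance column (threshold 0.05); a Benjamini-Hochberg
    ``bh_q`` column is emitted additionally as an extension.  Genes with
    zero variance are flagged (``r`` is NaN).
    """
    if panel is None:
        panel = CA_CORRELATION_PANEL
    if anchor_gene not in matrix.index:
        raise KeyError(f"anchor gene {anchor_gene!r} absent from matrix")
    anchor = matrix.loc[anchor_gene].to_numpy(dtype=float)
    records = []
    for gene in panel:
        if gene == anchor_gene or gene not in matrix.index:
            continue
        y = matrix.loc[gene].to_numpy(dtype=float)
        ok = np.isfinite(anchor) & np.isfinite(y)
        n_used = int(ok.sum())
        if n_used < 3:
            raise ValueError(
                f"fewer than 3 pairwise-complete observations for {gene}"
            )
        if np.std(y[ok]) == 0 or np.std(anchor[ok]) == 0:
            records.append((gene, np.nan, np.nan, n_used, True))
            continue
        r, p = stats.pearsonr(anchor[ok], y[ok])
        records.append((gene, float(r), float(p), n_used, False))
    out = pd.DataFrame(
        records, columns=["gene", "pearson_r", "p_value", "n_used",
                          "zero_variance"]
    )
    finite = out["p_value"].notna()
    out["bh_q"] = np.nan
    if finite.any():
        out.loc[finite, "bh_q"] = multipletests(
            out.loc[finite, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["significant"] = out["p_value"] < 0.05
    return out.sort_values("pearson_r", ascending=False,
                           na_position="last").reset_index(drop=True)


@dataclass
class CAITable:
    """Per-sample cumulative centrosome amplification index."""

    values: pd.DataFrame        # columns: sample_id, cai
    genes_used: list
    genes_missing: list


def cai(matrix: pd.DataFrame, panel="results") -> CAITable:
    """Cumulative centrosome amplification index: per-sample sum of log2
    expression over the panel genes present in the matrix.  Missing panel
    genes are reported, never imputed."""
    if isinstance(panel, str):
        try:
            panel = CAI_PANELS[panel]
        except KeyError:
            raise KeyError(
                f"unknown CAI preset {panel!r}; choose from {sorted(CAI_PANELS)}"
            ) from None
    used = [g for g in panel if g in matrix.index]
    missing = [g for g in panel if g not in matrix.index]
    if not used:
        raise ValueError(f"no CAI panel gene present in matrix (panel={panel})")
    sums = matrix.loc[used].sum(axis=0, skipna=False)
    values = pd.DataFrame({"sample_id": matrix.columns, "cai": sums.to_numpy()})
    return CAITable(values=values, genes_used=used, genes_missing=missing)
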