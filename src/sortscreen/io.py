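"""Reading and writing of screen tables, and exact-match protospacer counting.

All tabular interchange is delimited text (tab by default) with a header row.
Three table kinds are handled:

* **library tables** — the sgRNA-to-gene map: columns ``sgrna_id``,
  ``protospacer``, ``target_gene``, ``is_ntc``, ``sublibrary``.
* **bin-count tables** — per-sgRNA read counts in the two sorted bins:
  columns ``sgrna_id``, ``count_low``, ``count_high``.
* **result tables** — per-gene statistics written by the scoring stage.

Protospacer counting against a FASTQ file is exact-match only: a read is
assigned to an sgRNA when the subsequence ``read[offset:offset+length]``
equals its protospacer; anything else is tallied as unassigned.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ValidationError

logger = logging.getLogger(__name__)

LIBRARY_COLUMNS = ["sgrna_id", "protospacer", "target_gene", "is_ntc", "sublibrary"]
COUNT_COLUMNS = ["sgrna_id", "count_low", "count_high"]

#: Fixed column order for written gene/quasi-gene result tables.
RESULT_COLUMNS = [
    "gene",
    "sublibrary",
    "n_sgrnas",
    "phenotype",
    "p_value",
    "score",
    "norm_score",
    "is_hit",
    "direction",
    "low_confidence",
]

_NTC_PREFIXES = ("ntc", "non-targeting", "non_targeting", "nontargeting")
_DNA_ALPHABET = frozenset("ACGT")


def _flag_ntc(gene: str) -> bool:
    return str(gene).lower().startswith(_NTC_PREFIXES)


def validate_library(library: pd.DataFrame) -> pd.DataFrame:
    """Validate a library table in place and return it.

    Enforces: unique ``sgrna_id``, ACGT-only protospacers of one common
    length, NTC rows carry no target gene, and every non-NTC gene has at
    least one sgRNA (guaranteed by construction of the table).
    """
    missing = [c for c in LIBRARY_COLUMNS if c not in library.columns]
    if missing:
        raise ValidationError(f"library table missing columns: {missing}")
    dup = library["sgrna_id"][library["sgrna_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sgrna_id values: {sorted(set(dup))[:10]}")
    protos = library["protospacer"].astype(str)
    bad = protos[~protos.map(lambda s: set(s) <= _DNA_ALPHABET)]
    if len(bad):
        raise ValidationError(
            f"non-ACGT protospacer for sgRNAs: "
            f"{library.loc[bad.index, 'sgrna_id'].tolist()[:10]}"
        )
    lengths = protos.str.len().unique()
    if len(lengths) > 1:
        raise ValidationError(f"mixed protospacer lengths in library: {sorted(lengths)}")
    library["is_ntc"] = library["is_ntc"].astype(bool)
    return library


def read_library(path: str | Path, sep: str = "\t", ntc_pattern: str | None = None) -> pd.DataFrame:
    """Read and validate an sgRNA library table.

    NTC rows are detected from the ``is_ntc`` column when present; otherwise
    from the gene name, which is matched case-insensitively against the
    prefixes "NTC" / "non-targeting" (or ``ntc_pattern`` if given).
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "is_ntc" in df.columns:
        df["is_ntc"] = df["is_ntc"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
    else:
        if ntc_pattern is not None:
            df["is_ntc"] = df["target_gene"].str.lower().str.startswith(ntc_pattern.lower())
        else:
            df["is_ntc"] = df["target_gene"].map(_flag_ntc)
    if "sublibrary" not in df.columns:
        df["sublibrary"] = "lib0"
    df = df[LIBRARY_COLUMNS]
    return validate_library(df)


def write_library(library: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    library[LIBRARY_COLUMNS].to_csv(path, sep=sep, index=False)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_protospacers(
    fastq_path: str | Path,
    library: pd.DataFrame,
    offset: int,
    length: int | None = None,
) -> tuple[dict[str, int], int]:
    """Count exact protospacer matches in a FASTQ file.

    Each read's subsequence ``read[offset:offset+length]`` (0-based,
    end-exclusive) is looked up against the library's protospacers; an exact
    match increments that sgRNA, anything else — including reads shorter
    than ``offset+length`` — is tallied as unassigned.

    Returns ``(counts, unassigned)`` where ``counts`` maps every library
    sgrna_id to its read count (zero-filled).
    """
    proto_len = int(library["protospacer"].str.len().iloc[0])
    if length is None:
        length = proto_len
    if length != proto_len:
        raise ValidationError(
            f"requested match length {length} != library protospacer length {proto_len}"
        )
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    lookup = dict(zip(library["protospacer"], library["sgrna_id"]))
    counts = {sg: 0 for sg in library["sgrna_id"]}
    unassigned = 0
    total = 0
    end = offset + length
    with _open_maybe_gzip(fastq_path) as handle:
        try:
            for _title, seq, _qual in FastqGeneralIterator(handle):
                total += 1
                sg = lookup.get(seq[offset:end].upper()) if len(seq) >= end else None
                if sg is None:
                    unassigned += 1
                else:
                    counts[sg] += 1
        except ValueError as exc:
            raise ValidationError(
                f"malformed FASTQ record around record {total + 1} in {fastq_path}: {exc}"
            ) from exc
    if total == 0:
        logger.warning("FASTQ file %s contained no reads; all counts zero", fastq_path)
    assert sum(counts.values()) + unassigned == total  # read conservation
    return counts, unassigned


def read_counts(
    path: str | Path, library: pd.DataFrame, sep: str = "\t", screen_id: str = "screen"
) -> pd.DataFrame:
    """Read a per-bin count table and align it to the library.

    sgRNAs present in the library but absent from the file receive counts
    (0, 0) with a log line; ids not in the library are a hard error.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"counts table missing columns: {missing}")
    dup = df["sgrna_id"][df["sgrna_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sgrna_id in counts: {sorted(set(dup))[:10]}")
    unknown = set(df["sgrna_id"]) - set(library["sgrna_id"])
    if unknown:
        raise ValidationError(
            f"count table contains ids not in the library: {sorted(unknown)[:10]}"
        )
    for col in ("count_low", "count_high"):
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0, "sgrna_id"].tolist()[:10]
            raise ValidationError(f"negative {col} for sgRNAs: {bad}")
    aligned = library[["sgrna_id"]].merge(df[COUNT_COLUMNS], on="sgrna_id", how="left")
    n_absent = int(aligned["count_low"].isna().sum())
    if n_absent:
        logger.info("%d library sgRNAs absent from %s; zero-filled", n_absent, path)
    aligned = aligned.fillna({"count_low": 0, "count_high": 0})
    aligned[["count_low", "count_high"]] = aligned[["count_low", "count_high"]].astype(int)
    aligned["screen_id"] = screen_id
    if aligned["count_low"].sum() <= 0 or aligned["count_high"].sum() <= 0:
        raise ValidationError("each bin must have a positive read total")
    return aligned


def write_counts(counts: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep=sep, index=False)


def write_results(results: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a gene/quasi-gene result table with the fixed documented column order."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    # %.17g guarantees the written decimal text reads back bit-for-bit
    results[cols].to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_results(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_screen_result(result, outdir: str | Path, sep: str = "\t") -> None:
    """Write a ScreenResult as two TSVs plus a JSON parameter sidecar.

    Files: ``genes.tsv``, ``quasi_genes.tsv``, ``params.json`` (the sidecar
    records every parameter and hit threshold, sufficient to regenerate the
    result from the raw counts).
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_results(result.genes, outdir / "genes.tsv", sep=sep)
    write_results(result.quasi, outdir / "quasi_genes.tsv", sep=sep)
    sidecar = {"screen_id": result.screen_id, "params": _json_safe(result.params)}
    (outdir / "params.json").write_text(json.dumps(sidecar, sort_keys=True, indent=2) + "\n")


def read_screen_result(outdir: str | Path, sep: str = "\t"):
    """Read a ScreenResult previously written by :func:`write_screen_result`."""
    import json

    from .stats import ScreenResult

    outdir = Path(outdir)
    sidecar = json.loads((outdir / "params.json").read_text())
    return ScreenResult(
        screen_id=sidecar["screen_id"],
        genes=pd.read_csv(outdir / "genes.tsv", sep=sep, float_precision="round_trip"),
        quasi=pd.read_csv(outdir / "quasi_genes.tsv", sep=sep, float_precision="round_trip"),
        params=sidecar["params"],
    )
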