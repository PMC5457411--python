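"""File formats: FASTA/FASTQ, TSV interchange tables, YAML configs, VCF export.

Every table written by the toolkit starts with a ``#`` metadata line
recording the tool version and a hash of the originating configuration, so
results remain traceable to their run; readers skip such comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simdata import ConfigError, ExperimentConfig, SimRead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_table",
    "read_table",
    "write_truth_table",
    "load_config",
    "save_config",
    "config_hash",
    "write_vcf",
]


def read_fasta(path) -> tuple:
    """First record of a FASTA file as ``(name, sequence)``."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def write_fasta(path, name: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fastq(path):
    """Yield ``(name, sequence, quality)`` triples from a FASTQ file."""
    with open(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(path, reads) -> None:
    """Write ``SimRead``-like records (name, sequence, quality) as FASTQ."""
    with open(path, "w") as handle:
        for r in reads:
            handle.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def _version() -> str:
    from . import __version__
    return __version__


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping or dataclass."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _metadata_line(config=None) -> str:
    tag = f" config={config_hash(config)}" if config is not None else ""
    return f"# umifid v{_version()}{tag}"


def write_table(path, frame: pd.DataFrame, config=None) -> None:
    """TSV with a leading ``#`` metadata line (version + config hash)."""
    with open(path, "w") as handle:
        handle.write(_metadata_line(config) + "\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_truth_table(path, molecules, config=None) -> None:
    """Ground-truth error TSV: umi, stage (LA|PCR1), position, ref, alt, lineage_depth."""
    rows = []
    for mol in molecules:
        for stage, errors in (("LA", mol.la_errors), ("PCR1", mol.pcr1_errors)):
            for pos, ref, alt in errors:
                rows.append((mol.umi, stage, pos, ref, alt, mol.lineage_depth))
    frame = pd.DataFrame(
        rows, columns=["umi", "stage", "position", "ref", "alt", "lineage_depth"]
    )
    write_table(path, frame, config)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)}


def load_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from YAML, naming any offending key."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return ExperimentConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(path, config: ExperimentConfig) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(dataclasses.asdict(config), handle, sort_keys=True)


def write_vcf(path, calls: pd.DataFrame, template_name: str, template: str,
              config=None) -> None:
    """Minimal VCF export of the variant table for interoperability.

    Calls are template-relative counts over consensus molecules, not
    genotypes; INFO carries UMI_COUNT, COVERAGE and FREQ.
    """
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write(f"##source=umifid_v{_version()}\n")
        if config is not None:
            handle.write(f"##umifid_config={config_hash(config)}\n")
        handle.write(f"##contig=<ID={template_name},length={len(template)}>\n")
        handle.write('##INFO=<ID=UMI_COUNT,Number=1,Type=Integer,'
                     'Description="Consensus sequences carrying the substitution">\n')
        handle.write('##INFO=<ID=COVERAGE,Number=1,Type=Integer,'
                     'Description="Consensus sequences covering the position">\n')
        handle.write('##INFO=<ID=FREQ,Number=1,Type=Float,'
                     'Description="UMI-level substitution frequency">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in calls.sort_values(["position", "alt"]).itertuples(index=False):
            info = (f"UMI_COUNT={rec.umi_count};COVERAGE={rec.coverage};"
                    f"FREQ={rec.frequency:.6g}")
            handle.write(
                f"{template_name}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\n"
            )
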