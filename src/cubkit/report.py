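"""One-shot analysis battery: composition -> RSCU -> ENC/neutrality ->
adaptation -> dinucleotides -> PCA, emitted as a tidy TSV/JSON bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adaptation import adaptation_scores, load_host_reference, sid
from .composition import composition_batch
from .dinucleotide import dinucleotide_batch
from .enc_neutrality import (
    NeutralityFitError,
    enc_record,
    neutrality_fit,
    neutrality_points,
)
from .genetics import CubkitError, count_codons, validate_fasta
from .multivariate import pca_rscu
from .rscu import coincidence_analysis, mean_rscu, representation_calls, rscu_from_counts

logger = logging.getLogger(__name__)

TSV_DECIMALS = 3


@dataclass
class RunConfig:
    fasta: str
    out_dir: str = "cubkit_report"
    group_by: str | None = None  # TSV: id <tab> group
    hosts: list[str] = field(default_factory=list)
    rscu_over: float = 1.6
    rscu_under: float = 0.6
    dinuc_over: float = 1.23
    dinuc_under: float = 0.78
    enc_bias_cutoff: float = 35.0
    circular: bool = False
    pca_axes: int = 2
    seed: int = 0
    frame_policy: str = "strict"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{TSV_DECIMALS}f")


def _load_groups(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "group"], dtype=str)
    return dict(zip(df["id"], df["group"]))


def run_report(config: RunConfig) -> dict:
    """Run the full battery and write the results bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", asdict(config))

    seqs, validation = validate_fasta(config.fasta, config.frame_policy)
    _write_tsv(pd.DataFrame(validation), out / "validation.tsv")
    if not seqs:
        raise CubkitError("no valid sequences; see validation.tsv")

    groups = _load_groups(config.group_by) if config.group_by else {}
    by_group: dict[str, list] = {}
    for s in seqs:
        by_group.setdefault(groups.get(s.id, "all"), []).append(s)

    # composition
    comp_rows = composition_batch(seqs)
    _write_tsv(pd.DataFrame(comp_rows), out / "composition.tsv")

    # per-sequence RSCU and group profiles
    counts = {s.id: count_codons(s) for s in seqs}
    profiles = {s.id: rscu_from_counts(counts[s.id]) for s in seqs}
    code = next(iter(profiles.values())).code
    rscu_df = pd.DataFrame(
        [
            {"id": sid_, **{c: p.values[c] for c in code.sense_codons}}
            for sid_, p in profiles.items()
        ]
    )
    _write_tsv(rscu_df, out / "rscu.tsv")

    group_profiles = {
        g: mean_rscu([profiles[s.id] for s in members])
        for g, members in by_group.items()
    }

    # ENC / neutrality
    enc_rows = [enc_record(s).as_dict() for s in seqs]
    _write_tsv(pd.DataFrame(enc_rows), out / "enc.tsv")
    neutrality_rows = []
    for g, members in by_group.items():
        try:
            fit = neutrality_fit(neutrality_points(members))
            neutrality_rows.append({"group": g, **fit.as_dict()})
        except NeutralityFitError as err:
            neutrality_rows.append({"group": g, "error": str(err)})
    _write_tsv(pd.DataFrame(neutrality_rows), out / "neutrality.tsv")

    # hosts: adaptation + SiD + coincidence
    summary_hosts = {}
    adapt_rows = []
    for host_src in config.hosts:
        host = load_host_reference(host_src)
        for s in seqs:
            sc = adaptation_scores(s.id, counts[s.id], host)
            adapt_rows.append(asdict(sc))
        host_summary = {}
        for g, prof in group_profiles.items():
            entry = {"sid": sid(prof, host.rscu)}
            if not prof.unobserved_families:
                rep = coincidence_analysis(prof, host.rscu)
                entry.update(
                    n_coincidence=rep.n_coincidence,
                    n_antagonism=rep.n_antagonism,
                    ending_census=dict(rep.ending_census),
                )
            host_summary[g] = entry
        summary_hosts[host.name] = host_summary
    if adapt_rows:
        _write_tsv(pd.DataFrame(adapt_rows), out / "adaptation.tsv")

    # dinucleotides
    mode = "circular" if config.circular else "linear"
    dinuc_profiles, dinuc_summary = dinucleotide_batch(seqs, mode)
    dinuc_df = pd.DataFrame(
        [{"id": p.id, **p.odds} for p in dinuc_profiles]
    )
    _write_tsv(dinuc_df, out / "dinucleotide.tsv")

    # PCA (needs >= 2 complete profiles)
    pca_summary = None
    complete = [
        (sid_, p) for sid_, p in profiles.items() if not p.unobserved_families
    ]
    if len(complete) >= 2:
        result = pca_rscu(
            [p for _, p in complete],
            n_axes=config.pca_axes,
            ids=[sid_ for sid_, _ in complete],
        )
        pca_df = pd.DataFrame(result.coordinates, columns=[
            f"axis{i + 1}" for i in range(result.n_axes)
        ])
        pca_df.insert(0, "id", list(result.ids))
        pca_df.insert(1, "group", [groups.get(i, "all") for i in result.ids])
        _write_tsv(pca_df, out / "pca.tsv")
        pca_summary = {
            "explained_variance_pct": [float(v) for v in result.explained_variance_pct],
        }

    # representation calls on group profiles
    representation = {
        g: {
            c: call
            for c, call in representation_calls(
                prof, over=config.rscu_over, under=config.rscu_under
            ).items()
            if call in ("over", "under")
        }
        for g, prof in group_profiles.items()
    }

    summary = {
        "tool": "cubkit",
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_sequences": len(seqs),
        "groups": {g: len(m) for g, m in by_group.items()},
        "hosts": summary_hosts,
        "neutrality": neutrality_rows,
        "dinucleotide_summary": dinuc_summary,
        "representation": representation,
        "pca": pca_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return summary
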