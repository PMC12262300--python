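"""Readers and writers for the pipeline's plain-text and NPZ interchange formats.

Formats
-------
reactions TSV     reaction_id, smiles (atom-mapped reaction SMILES), optional
                  rc_reactant_atoms / rc_product_atoms (semicolon-separated
                  0-based global indices, overriding derivation)
curation TSV      protein_id, reaction_id, evidence, is_subunit, is_transport
pairs TSV         protein_id, reaction_id, label, fold
split TSV         entity_id, fold, cv_fold, declared_stratum, realized_max_sim
similarity TSV    id_a, id_b, score (long format, upper triangle) plus an NPZ
                  container with the id order
protein FASTA     sequences keyed by id (via biopython)
embeddings NPZ    one array per protein id
operators TSV     name, reaction-SMARTS pattern pair (one template per line)
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reaction_core import (
    CurationRecord,
    OperatorTemplate,
    Reaction,
    derive_rc_from_map,
    parse_reaction,
    reaction_smiles,
)
from .scoring_model import ProteinRecord
from .similarity import SimilarityMatrix
from .splitting import PairDataset, SplitAssignment

__all__ = [
    "read_reactions_tsv",
    "write_reactions_tsv",
    "read_curation_tsv",
    "read_operators_tsv",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "write_split_tsv",
    "read_fasta",
    "write_fasta",
    "read_embeddings_npz",
    "write_embeddings_npz",
    "write_similarity",
    "read_similarity",
    "write_embedding_tsv",
]


def _parse_idx_set(text) -> frozenset[int]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return frozenset()
    return frozenset(int(t) for t in str(text).split(";"))


def read_reactions_tsv(path, derive_rc: bool = True, drop_empty_rc: bool = True) -> list[Reaction]:
    """Load reactions; derive RCs from atom maps unless overridden per row.

    Identity reactions (empty RC) are dropped with a warning when
    ``drop_empty_rc`` is set — they carry no transformation to learn.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        r = parse_reaction(row["smiles"], row["reaction_id"])
        rc_r = _parse_idx_set(row.get("rc_reactant_atoms"))
        rc_p = _parse_idx_set(row.get("rc_product_atoms"))
        if rc_r or rc_p:
            r.rc_reactant_atoms, r.rc_product_atoms = rc_r, rc_p
        elif derive_rc:
            r = derive_rc_from_map(r)
            if r.empty_rc:
                if drop_empty_rc:
                    warnings.warn(
                        f"dropping identity reaction {r.id!r} (empty RC)"
                    )
                    continue
        out.append(r)
    return out


def write_reactions_tsv(path, reactions: list[Reaction]) -> None:
    rows = []
    for r in reactions:
        rows.append(
            {
                "reaction_id": r.id,
                "smiles": reaction_smiles(r, keep_maps=True),
                "rc_reactant_atoms": ";".join(map(str, sorted(r.rc_reactant_atoms))),
                "rc_product_atoms": ";".join(map(str, sorted(r.rc_product_atoms))),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_curation_tsv(path) -> list[CurationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CurationRecord(
            protein_id=str(row["protein_id"]),
            reaction_id=str(row["reaction_id"]),
            evidence=str(row["evidence"]),
            is_subunit=bool(row["is_subunit"]),
            is_transport=bool(row["is_transport"]),
        )
        for _, row in df.iterrows()
    ]


def read_operators_tsv(path) -> list[OperatorTemplate]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        OperatorTemplate(name=row["name"], smarts=row["smarts"])
        for _, row in df.iterrows()
    ]


def read_pairs_tsv(path) -> PairDataset:
    df = pd.read_csv(path, sep="\t", dtype={"label": int})
    ds = PairDataset()
    for _, row in df.iterrows():
        ds.pairs.append(
            (str(row["protein_id"]), str(row["reaction_id"]), int(row["label"]),
             str(row["fold"]))
        )
    return ds


def write_pairs_tsv(path, ds: PairDataset) -> None:
    pd.DataFrame(
        ds.pairs, columns=["protein_id", "reaction_id", "label", "fold"]
    ).to_csv(path, sep="\t", index=False)


def write_split_tsv(path, assignment: SplitAssignment) -> None:
    pd.DataFrame(assignment.to_rows()).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_embeddings_npz(path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}


def write_embeddings_npz(path, embeddings: dict[str, np.ndarray]) -> None:
    np.savez(path, **embeddings)


def load_proteins(fasta_path, npz_path) -> list[ProteinRecord]:
    seqs = read_fasta(fasta_path)
    embs = read_embeddings_npz(npz_path)
    missing = sorted(set(seqs) - set(embs))
    if missing:
        raise KeyError(f"no embedding for proteins: {missing[:5]}")
    return [ProteinRecord(id=p, sequence=s, embedding=embs[p]) for p, s in sorted(seqs.items())]


def write_similarity(tsv_path, npz_path, m: SimilarityMatrix) -> None:
    rows = []
    for i in range(len(m.ids)):
        for j in range(i + 1, len(m.ids)):
            rows.append(
                {"id_a": m.ids[i], "id_b": m.ids[j], "score": f"{m.scores[i, j]:.6f}"}
            )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    np.savez(
        npz_path,
        ids=np.array(m.ids),
        scores=m.scores,
        metric=np.array(m.metric),
    )


def read_similarity(npz_path) -> SimilarityMatrix:
    with np.load(npz_path) as z:
        return SimilarityMatrix(
            ids=[str(x) for x in z["ids"]],
            scores=z["scores"],
            metric=str(z["metric"]),
        )


def write_embedding_tsv(path, embeddings: dict[str, np.ndarray]) -> None:
    """Reaction/protein embeddings as TSV: id then the vector components."""
    with open(path, "w") as fh:
        for key in sorted(embeddings):
            vec = "\t".join(f"{v:.8g}" for v in embeddings[key])
            fh.write(f"{key}\t{vec}\n")
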