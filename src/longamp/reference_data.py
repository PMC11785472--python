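"""Synthetic mini-reference for desk-scale taxonomy tests and simulation.

This is NOT real database data: sequences are generated deterministically
from per-genus seeds. Each genus gets a random ancestor 16S sequence; its
species are derived from the ancestor by ~2% substitutions, so congeneric
species sit near the genus identity threshold while different genera are
unrelated (random-sequence identity, far below the phylum threshold). The
taxon names mirror lineages commonly found in marine cyanobacterial culture
microbiomes (hosts plus heterotrophic satellites).
"""

from __future__ import annotations

import zlib
from functools import lru_cache

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# genus -> (lineage through genus, species epithets, 16S length)
_GENERA: dict[str, tuple[str, tuple[str, ...], int]] = {
    "Coleofasciculus": (
        "Bacteria;Cyanobacteria;Cyanobacteriia;Cyanobacteriales;Coleofasciculaceae;Coleofasciculus",
        ("chthonoplastes", "sp-SPW", "sp-WW12"), 1420),
    "Salileptolyngbya": (
        "Bacteria;Cyanobacteria;Cyanobacteriia;Cyanobacteriales;Leptolyngbyaceae;Salileptolyngbya",
        ("sp-WW4",), 1418),
    "Balneola": (
        "Bacteria;Balneolota;Balneolia;Balneolales;Balneolaceae;Balneola",
        ("alkaliphila", "vulgaris"), 1412),
    "Gracilimonas": (
        "Bacteria;Balneolota;Balneolia;Balneolales;Balneolaceae;Gracilimonas",
        ("tropica",), 1411),
    "Imperialibacter": (
        "Bacteria;Bacteroidota;Cytophagia;Cytophagales;Flammeovirgaceae;Imperialibacter",
        ("roseus", "sp-C2"), 1416),
    "Ekhidna": (
        "Bacteria;Bacteroidota;Cytophagia;Cytophagales;Flammeovirgaceae;Ekhidna",
        ("lutea",), 1415),
    "Fulvivirga": (
        "Bacteria;Bacteroidota;Cytophagia;Cytophagales;Fulvivirgaceae;Fulvivirga",
        ("kasyanovii", "imtechensis"), 1414),
    "Muricauda": (
        "Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;Flavobacteriaceae;Muricauda",
        ("ruestringensis", "aquimarina"), 1409),
    "Lewinella": (
        "Bacteria;Bacteroidota;Saprospiria;Saprospirales;Saprospiraceae;Lewinella",
        ("persica",), 1413),
    "Nitratireductor": (
        "Bacteria;Pseudomonadota;Alphaproteobacteria;Hyphomicrobiales;Phyllobacteriaceae;Nitratireductor",
        ("arenosus", "aquibiodomus"), 1421),
    "Roseitalea": (
        "Bacteria;Pseudomonadota;Alphaproteobacteria;Hyphomicrobiales;Rhizobiaceae;Roseitalea",
        ("porphyridii",), 1419),
    "Roseovarius": (
        "Bacteria;Pseudomonadota;Alphaproteobacteria;Rhodobacterales;Roseobacteraceae;Roseovarius",
        ("indicus", "mucosus", "tolerans"), 1417),
    "Marinovum": (
        "Bacteria;Pseudomonadota;Alphaproteobacteria;Rhodobacterales;Roseobacteraceae;Marinovum",
        ("algicola",), 1417),
    "Thalassospira": (
        "Bacteria;Pseudomonadota;Alphaproteobacteria;Rhodospirillales;Thalassospiraceae;Thalassospira",
        ("lucentensis", "profundimaris"), 1423),
    "Marinibaculum": (
        "Bacteria;Pseudomonadota;Alphaproteobacteria;Sneathiellales;Sneathiellaceae;Marinibaculum",
        ("pumilum",), 1420),
    "Ponticaulis": (
        "Bacteria;Pseudomonadota;Alphaproteobacteria;Caulobacterales;Hyphomonadaceae;Ponticaulis",
        ("koreensis",), 1415),
    "Hydrogenophaga": (
        "Bacteria;Pseudomonadota;Betaproteobacteria;Burkholderiales;Comamonadaceae;Hydrogenophaga",
        ("palleronii", "taeniospiralis"), 1422),
    "Marinobacter": (
        "Bacteria;Pseudomonadota;Gammaproteobacteria;Alteromonadales;Marinobacteraceae;Marinobacter",
        ("algicola", "salarius"), 1418),
    "Woeseia": (
        "Bacteria;Pseudomonadota;Gammaproteobacteria;Chromatiales;Woeseiaceae;Woeseia",
        ("oceani",), 1416),
    "Halioglobus": (
        "Bacteria;Pseudomonadota;Gammaproteobacteria;Cellvibrionales;Halieaceae;Halioglobus",
        ("japonicus",), 1417),
    "Rhodopirellula": (
        "Bacteria;Planctomycetota;Planctomycetia;Pirellulales;Pirellulaceae;Rhodopirellula",
        ("baltica",), 1425),
    "Ilumatobacter": (
        "Bacteria;Actinomycetota;Acidimicrobiia;Microtrichales;Ilumatobacteraceae;Ilumatobacter",
        ("fluminis", "coccineus"), 1410),
    "Gemmatimonas": (
        "Bacteria;Gemmatimonadota;Gemmatimonadetes;Gemmatimonadales;Gemmatimonadaceae;Gemmatimonas",
        ("aurantiaca",), 1419),
    "Caldilinea": (
        "Bacteria;Chloroflexota;Caldilineae;Caldilineales;Caldilineaceae;Caldilinea",
        ("aerophila",), 1421),
    "Spirochaeta": (
        "Bacteria;Spirochaetota;Spirochaetia;Spirochaetales;Spirochaetaceae;Spirochaeta",
        ("perfilievii",), 1424),
    "Luteolibacter": (
        "Bacteria;Verrucomicrobiota;Verrucomicrobiia;Verrucomicrobiales;Rubritaleaceae;Luteolibacter",
        ("pohnpeiensis",), 1412),
    "Bryobacter": (
        "Bacteria;Acidobacteriota;Bryobacteria;Bryobacterales;Bryobacteraceae;Bryobacter",
        ("aggregatus",), 1415),
    "Chlorobium": (
        "Bacteria;Chlorobiota;Chlorobia;Chlorobiales;Chlorobiaceae;Chlorobium",
        ("limicola",), 1413),
    "Bacillus": (
        "Bacteria;Bacillota;Bacilli;Bacillales;Bacillaceae;Bacillus",
        ("horikoshii",), 1408),
}


def _rng(label: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(label.encode()))


def _random_seq(label: str, length: int) -> np.ndarray:
    return _BASES[_rng(label).integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, label: str, rate: float) -> np.ndarray:
    rng = _rng(label)
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


@lru_cache(maxsize=1)
def mini_reference() -> list[tuple[str, str, str]]:
    """Return the packaged synthetic reference as (ref_id, lineage, sequence).

    Deterministic across sessions. Lineages are semicolon-delimited,
    domain through species.
    """
    entries = []
    for genus, (lineage, species, length) in _GENERA.items():
        ancestor = _random_seq(f"genus:{genus}", length)
        for sp in species:
            seq = _mutate(ancestor, f"species:{genus} {sp}", 0.02)
            ref_id = f"{genus}_{sp}".replace(" ", "_")
            entries.append((ref_id, f"{lineage};{genus} {sp}", seq.tobytes().decode()))
    return entries


def reference_fasta(path) -> None:
    """Write the mini-reference to FASTA with lineage-bearing headers."""
    with open(path, "w") as fh:
        for ref_id, lineage, seq in mini_reference():
            fh.write(f">{ref_id} {lineage}\n{seq}\n")


def reference_sequence(ref_id: str) -> str:
    for rid, _, seq in mini_reference():
        if rid == ref_id:
            return seq
    raise KeyError(ref_id)
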