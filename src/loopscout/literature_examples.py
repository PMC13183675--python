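"""Synthetic stand-in pathways modeled on published WikiPathways entries.

Real WikiPathways GPML files must be downloaded from the database; this
module instead generates small *synthetic* GPML documents whose topology
realizes the documented regulatory structure of several well-known
pathways, so the full parse -> cycle -> motif machinery can be exercised
and demonstrated offline.  Every document here is synthetic: node sets
are reduced to the regulatory backbone, layout is placeholder geometry,
and pathway identifiers carry a ``SYN-`` prefix to make the provenance
unmistakable.

Included stand-ins:

* :func:`igf1_akt_signaling_gpml` — IGF1-Akt signaling (WP3850-style):
  a PI3K/PDK1/AKT1/FoxO/MAFbx/mTORC1/S6K/IRS1 backbone with a SMAD2+SMAD3
  group, wired so the graph contains exactly five elementary cycles;
* :func:`cholesterol_biosynthesis_gpml` — cholesterol metabolism
  (WP4718-style): a linear sterol-biosynthesis conversion cascade,
  interleaved with anchors and closed by the canonical sterol-sensing
  negative feedback (25-hydroxycholesterol inhibits SREBF2, which
  stimulates biosynthetic enzymes), producing a 50-node
  representation-driven cycle whose regulatory core survives filtering;
* :func:`tp53_mdm2_pathways_gpml` — four pathway contexts (TP53
  network, glioblastoma, retinoblastoma, mesothelioma styles) that all
  embed the MDM2-TP53 negative feedback loop.
"""

from __future__ import annotations

from ._xmlbuild import GpmlBuilder

__all__ = [
    "igf1_akt_signaling_gpml",
    "cholesterol_biosynthesis_gpml",
    "tp53_mdm2_pathways_gpml",
]


def igf1_akt_signaling_gpml() -> bytes:
    """Synthetic IGF1-Akt signaling pathway (WP3850-style stand-in).

    The wiring yields exactly five elementary cycles: two long
    kinase-cascade cycles through IRS1/PI3K/PDK1/AKT1 (with and without
    MAFbx), the FoxO<->MAFbx two-cycle, and two mTORC1/Group1/AKT1
    feedback cycles.  ``Group1`` is a group vertex containing SMAD2 and
    SMAD3.
    """
    b = GpmlBuilder("SYN-WP3850-like")
    for gene in ("PI3K", "PDK1", "AKT1", "FoxO", "MAFbx", "S6K", "IRS1"):
        b.data_node(gene, gene, "GeneProduct")
    b.data_node("mTORC1", "mTORC1", "Complex")
    b.group("grp1")
    b.data_node("SMAD2", "SMAD2", "GeneProduct", group_ref="grp1")
    b.data_node("SMAD3", "SMAD3", "GeneProduct", group_ref="grp1")
    wiring = [
        ("IRS1", "PI3K", "mim-stimulation"),
        ("PI3K", "PDK1", "mim-stimulation"),
        ("PDK1", "AKT1", "mim-stimulation"),
        ("AKT1", "FoxO", "mim-inhibition"),
        ("FoxO", "MAFbx", "mim-stimulation"),
        ("MAFbx", "FoxO", "mim-stimulation"),
        ("FoxO", "mTORC1", "mim-inhibition"),
        ("MAFbx", "mTORC1", "mim-inhibition"),
        ("mTORC1", "S6K", "mim-stimulation"),
        ("S6K", "IRS1", "mim-inhibition"),
        ("mTORC1", "grp1", "mim-stimulation"),
        ("grp1", "AKT1", "mim-inhibition"),
    ]
    for k, (src, tgt, arrow) in enumerate(wiring, start=1):
        b.interaction(f"id{k}", src, tgt, arrow)
    return b.tobytes()


#: Sterol-biosynthesis intermediates for the conversion cascade; the
#: first is the cascade entry point (off-cycle), the last is cholesterol.
_STEROL_CHAIN = [
    "Acetoacetyl-CoA",
    "HMG-CoA",
    "Mevalonate",
    "Mevalonate-5-phosphate",
    "Mevalonate-5-pyrophosphate",
    "Isopentenyl pyrophosphate",
    "Dimethylallyl pyrophosphate",
    "Geranyl pyrophosphate",
    "Farnesyl pyrophosphate",
    "Squalene",
    "Squalene-2,3-epoxide",
    "Lanosterol",
    "4,4-Dimethylcholesta-8,14,24-trienol",
    "4,4-Dimethylcholesta-8,24-dienol",
    "4-Methylzymosterol-carboxylate",
    "3-Keto-4-methylzymosterol",
    "4-Methylzymosterol",
    "Zymosterone",
    "Zymosterol",
    "Cholesta-7,24-dienol",
    "7-Dehydrodesmosterol",
    "Desmosterol",
    "7-Dehydrocholesterol",
    "Cholesterol",
]


def cholesterol_biosynthesis_gpml() -> bytes:
    """Synthetic cholesterol-metabolism pathway (WP4718-style stand-in).

    A 24-step conversion cascade runs from acetoacetyl-CoA to
    cholesterol and on to 25-hydroxycholesterol, each conversion carrying
    an anchor point.  SREBF2 stimulates the biosynthetic enzymes (HMGCR,
    DHCR24, DHCR7), whose catalysis edges terminate on the anchors, and
    25-hydroxycholesterol inhibits SREBF2.  The resulting unfiltered
    graph contains a representation-driven inhibition-bearing cycle of
    exactly 50 nodes (metabolites, anchors, SREBF2, HMGCR); after the
    regulatory filter only the sterol -| SREBF2 -> enzymes core remains,
    and no cycle survives.
    """
    b = GpmlBuilder("SYN-WP4718-like")
    mets = [f"m{i + 1}" for i in range(len(_STEROL_CHAIN))]
    for mid, name in zip(mets, _STEROL_CHAIN):
        b.data_node(mid, name, "Metabolite")
    b.data_node("oxysterol", "25-Hydroxycholesterol", "Metabolite")
    b.data_node("SREBF2", "SREBF2", "GeneProduct")
    for enzyme in ("HMGCR", "DHCR24", "DHCR7"):
        b.data_node(enzyme, enzyme, "GeneProduct")

    # conversion cascade with one anchor per step; the last step is
    # cholesterol -> 25-hydroxycholesterol
    targets = mets[1:] + ["oxysterol"]
    for i, (src, tgt) in enumerate(zip(mets, targets), start=1):
        b.interaction(f"conv{i}", src, tgt, "mim-conversion", anchors=(f"a{i}",))

    b.interaction("stim1", "SREBF2", "HMGCR", "mim-stimulation")
    b.interaction("stim2", "SREBF2", "DHCR24", "mim-stimulation")
    b.interaction("stim3", "SREBF2", "DHCR7", "mim-stimulation")
    b.interaction("cat1", "HMGCR", "a1", "mim-catalysis")
    b.interaction("cat2", "DHCR24", "a20", "mim-catalysis")
    b.interaction("cat3", "DHCR7", "a24", "mim-catalysis")
    b.interaction("inhib1", "oxysterol", "SREBF2", "mim-inhibition")
    return b.tobytes()


def tp53_mdm2_pathways_gpml() -> dict[str, bytes]:
    """Four synthetic pathway contexts embedding the MDM2-TP53 loop.

    Styled on the TP53 network, glioblastoma, retinoblastoma-in-cancer,
    and pleural-mesothelioma pathways.  Each graph contains the
    TP53 -> MDM2 (stimulation) / MDM2 -| TP53 (inhibition) negative
    feedback two-cycle plus pathway-specific context nodes that do not
    add further cycles.
    """
    contexts = {
        "SYN-WP1742-like": [("CDKN1A", "mim-stimulation"), ("BAX", "mim-stimulation")],
        "SYN-WP2261-like": [("EGFR", None), ("PTEN", "mim-stimulation")],
        "SYN-WP2446-like": [("RB1", None), ("E2F1", "mim-inhibition")],
        "SYN-WP5087-like": [("CDKN2A", None), ("BAP1", None)],
    }
    documents: dict[str, bytes] = {}
    for pid, extras in contexts.items():
        b = GpmlBuilder(pid)
        b.data_node("TP53", "TP53", "GeneProduct")
        b.data_node("MDM2", "MDM2", "GeneProduct")
        b.interaction("t2m", "TP53", "MDM2", "mim-stimulation")
        b.interaction("m2t", "MDM2", "TP53", "mim-inhibition")
        for k, (gene, arrow) in enumerate(extras, start=1):
            b.data_node(gene, gene, "GeneProduct")
            # context genes hang off TP53 without returning to it
            b.interaction(f"ctx{k}", "TP53", gene, arrow)
        documents[pid] = b.tobytes()
    return documents
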