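"""RecPhyloXML serialization of a fitted reconciliation.

Writes the species tree and the gene tree with per-node ``<eventsRec>``
annotations (speciation, duplication, branchingOut/transferBack, loss,
leaf), following the recPhyloXML exchange format for reconciled gene trees.
Lineage movements are spelled out as speciationLoss / transfer+loss pairs
on the path between consecutive gene-tree events.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .reconcile import ReconciliationResult

__all__ = ["to_recphyloxml"]


def _species_clade(node) -> ET.Element:
    clade = ET.Element("clade")
    ET.SubElement(clade, "name").text = node.name
    for c in node.children:
        clade.append(_species_clade(c))
    return clade


def to_recphyloxml(result: ReconciliationResult) -> str:
    tree = result.model.species_tree
    root = ET.Element("recPhylo")
    sp = ET.SubElement(root, "spTree")
    sp_phy = ET.SubElement(sp, "phylogeny", rooted="true")
    sp_phy.append(_species_clade(tree.root))

    rec = ET.SubElement(root, "recGeneTree")
    phy = ET.SubElement(rec, "phylogeny", rooted="true")

    # events grouped by the gene lineage they belong to, in emitted order
    per_lineage: dict[str, list] = {}
    for e in result.events:
        per_lineage.setdefault(e.gene_node, []).append(e)

    def gene_clade(node) -> ET.Element:
        clade = ET.Element("clade")
        ET.SubElement(clade, "name").text = node.label
        events = ET.SubElement(clade, "eventsRec")
        # path events (speciation-loss / transfer-loss) precede the node event
        for ev in per_lineage.get(node.label, []):
            if not node.is_leaf and ev is per_lineage[node.label][-1]:
                break
            if ev.event == "speciation":
                ET.SubElement(
                    events, "speciationLoss", speciesLocation=ev.species_branch
                )
            elif ev.event == "transfer":
                ET.SubElement(events, "branchingOut", speciesLocation=ev.donor)
                ET.SubElement(
                    events, "transferBack", destinationSpecies=ev.recipient
                )
            # the paired loss lives on the pruned side; recPhyloXML encodes it
            # inside the compound speciationLoss / branchingOut records
        if node.is_leaf:
            ET.SubElement(
                events, "leaf", speciesLocation=result.leaf_mapping[node.label]
            )
        else:
            branch, _, kind = result.node_positions[node.label]
            if kind == "S":
                ET.SubElement(events, "speciation", speciesLocation=branch)
            elif kind == "D":
                ET.SubElement(events, "duplication", speciesLocation=branch)
            else:
                ET.SubElement(events, "branchingOut", speciesLocation=branch)
            for c in node.children:
                clade.append(gene_clade(c))
        return clade

    gt = result.model.gene_tree
    if gt.root is not None:
        phy.append(gene_clade(gt.root))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
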