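"""Scan a sequence for potential N-glycosylation sites.

Every Asn is reported with its 5-residue context; ``canonical`` marks
the N-X-(T/S) sequon recognised by ER glycosyltransferases, and
``small_preceded`` marks an Ala or Gly immediately before the Asn — the
shared feature of the non-canonical glycosylation sites on chlorovirus
capsid proteins.
"""

from densitrace import sequon_scan

# toy sequence carrying one canonical site (ANTTP) and one
# non-canonical, glycine-preceded site (GNVFF)
seq = "MKANTTPLEDRGNVFFKQW"
print(f"sequence: {seq}\n")
print("pos  context  canonical  small-preceded")
for site in sequon_scan(seq):
    print(f"{site.position:>3}  {site.context:<7}  {str(site.canonical):<9}  {site.small_preceded}")
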