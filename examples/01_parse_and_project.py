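"""Parse a consensus map and a QTL file, then apply the placement rules.

Two of the three QTL below are incomplete: one lacks a position and CI
(both are filled from its flanking markers), one names a marker that is
not on the map (it is excluded, with a reason code).
"""

from metaqtl import filter_records, parse_map_file, parse_qtl_file

MAP = """\
chromosome\tmarker\tdistance_from_previous_cM
c1\tNAU1042\t0
c1\tBNL3580\t12.5
c1\tCIR018\t9.0
c1\tTMB0471\t18.0
"""

QTL = """\
map_name\tqtl_name\tstudy_id\tchromosome\ttrait\tlod\tr2\tmethod\tposition_cM\tci_lo_cM\tci_hi_cM\tflank_left\tflank_right
cmd\tqFS-c1-1\tsmith2009\tc1\tFS\t3.4\t0.12\tCIM\t15.0\t10.0\t20.0\t\t
cmd\tqMicro-c1-1\tsmith2009\tc1\tMicronaire\t2.9\t0.08\tMQM\t\t\t\tBNL3580\tCIR018
cmd\tqFL-c1-1\tchen2012\tc1\tFL\t4.1\t\tCIM\t\t\t\tNAU9999\tCIR018
"""

cmap = parse_map_file(MAP)
print(f"c1 spans {cmap.length('c1'):.1f} cM with {len(cmap.markers['c1'])} markers")

report = filter_records(parse_qtl_file(QTL), cmap)
for rec in report.kept:
    print(
        f"kept {rec.qtl_name}: position {rec.position:.2f} cM, "
        f"CI [{rec.ci_lo:.2f}, {rec.ci_hi:.2f}]"
    )
for rec, reason in report.excluded:
    print(f"excluded {rec.qtl_name}: {reason.value}")

# The micronaire QTL had no reported position: it lands at the midpoint of
# its flanking markers (12.5 and 21.5 cM -> 17.0) and inherits their span
# as its confidence interval. The fiber-length QTL cites a marker absent
# from the consensus map, the standard reason for dropping a record.
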