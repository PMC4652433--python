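"""Independent brute-force evaluator of the lifetime-risk rules.

Re-checks every rule predicate naively against the raw relative list with
no code shared with famrisk.risk.  Role→side, role→degree and
role→generation facts are restated here from first principles so that a
mapping error in the package cannot hide.
"""

MOTHER_SIDE_ROLES = {
    "mother",
    "maternal_grandmother",
    "maternal_grandfather",
    "maternal_aunt_uncle",
    "maternal_aunt_uncle_child",
}
FATHER_SIDE_ROLES = {
    "father",
    "paternal_grandmother",
    "paternal_grandfather",
    "paternal_aunt_uncle",
    "paternal_aunt_uncle_child",
}
YOUR_SIDE_ROLES = {"sibling", "child"}
FDR_ROLES = {"mother", "father", "sibling", "child"}
GENERATION = {
    "maternal_grandmother": 2,
    "maternal_grandfather": 2,
    "paternal_grandmother": 2,
    "paternal_grandfather": 2,
    "mother": 1,
    "father": 1,
    "maternal_aunt_uncle": 1,
    "paternal_aunt_uncle": 1,
    "sibling": 0,
    "maternal_aunt_uncle_child": 0,
    "paternal_aunt_uncle_child": 0,
    "child": -1,
}


def oracle_category(pedigree, cutoff_primary=55, cutoff_high=50,
                    amsterdam_rel=3, amsterdam_gen=2, cluster_min=2) -> str:
    """Return the expected category name for a pedigree by naive rule checks."""
    rows = [
        (
            r.role.value,
            r.history.affected,
            r.history.age_at_diagnosis,
            r.history.multiple_polyps,
            r.history.other_related_cancers,
            r.history.multiple_primary_crc,
        )
        for r in pedigree
    ]

    # potentially high: polyposis signal
    if any(polyps for (_, _, _, polyps, _, _) in rows):
        return "potentially_high"

    for side_roles in (MOTHER_SIDE_ROLES, FATHER_SIDE_ROLES):
        cluster = [
            row
            for row in rows
            if row[1] and (row[0] in side_roles or row[0] in YOUR_SIDE_ROLES)
        ]
        # Amsterdam-style: enough relatives across generations, one early
        if len(cluster) >= amsterdam_rel:
            gens = {GENERATION[row[0]] for row in cluster}
            early = [row for row in cluster if row[2] is not None and row[2] < cutoff_high]
            if len(gens) >= amsterdam_gen and early:
                return "potentially_high"
        # smaller cluster with an early onset / Lynch-spectrum signal
        if len(cluster) >= cluster_min:
            if any(
                (age is not None and age < cutoff_high) or other or multi
                for (_, _, age, _, other, multi) in cluster
            ):
                return "potentially_high"

    affected_fdr = [row for row in rows if row[1] and row[0] in FDR_ROLES]
    if any(age is not None and age < cutoff_primary for (_, _, age, _, _, _) in affected_fdr):
        return "moderately_increased"
    if len(affected_fdr) >= 2:
        return "moderately_increased"
    if len(affected_fdr) == 1:
        return "slightly_increased"
    return "average"
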