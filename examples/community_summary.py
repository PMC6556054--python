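"""Per-body-site community capability summary.

For each metadata tag, counts the organisms carrying it and the size of the
union of reactions catalyzable by those organisms, plus a grand-total row.
"""

from orgroutes import build_trp_fixture, summarize_by_tag

db = build_trp_fixture()
print(summarize_by_tag(db.org_matrix).to_string(index=False))

# Reaction counts are unions, not sums: a reaction carried by several
# organisms in a site counts once, and the total row is the union over all
# tagged organisms.
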