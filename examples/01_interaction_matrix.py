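"""Build the enzyme-fiber interaction matrix from the packaged bond catalogs.

Each dietary fiber is annotated with the glycosidic bond types it contains
and each GH/PL enzyme with the bonds it cleaves; the binary matrix marks
every (enzyme, fiber) pair sharing at least one bond type.
"""

from fiberdeg import build_interaction_matrix, load_default_catalogs

fibers, enzymes = load_default_catalogs()
matrix = build_interaction_matrix(fibers, enzymes)

print(f"{len(enzymes)} GH/PL enzymes x {len(fibers)} dietary fibers")
frame = matrix.to_frame()
print("cellulose is cleaved by:", list(frame.index[frame["Cel"] == 1]))
print("inulin is cleaved by:", list(frame.index[frame["Inu"] == 1]))
# Column sums = how many catalog enzymes can attack each fiber; a fiber with
# a higher sum aggregates evidence from more enzyme families in the IFDP.
print("\nenzymes per fiber:")
print(frame.sum(axis=0).sort_values(ascending=False).to_string())
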