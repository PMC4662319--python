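"""What the latent feasible set looks like for a tiny two-mark dataset.

Three recorded histories over two occasions: a type-1 record (1,0), a
type-2 record (0,2) and a type-1 record (1,1).  Because the two mark types
cannot be matched, the (1,0) or (1,1) record may or may not belong to the
same individual as (0,2); the constraint system below enumerates every
latent explanation.
"""

from latentmark import initialize_frequencies, process_data

obs, lmap = process_data([[1, 0], [0, 2], [1, 1]], "never")

print(f"records: {obs.n1} type-1, {obs.n2} type-2, {obs.n_known} known")
print(f"admissible latent histories ({lmap.n_histories}):")
for h, known in zip(lmap.histories, lmap.is_known):
    print("   ", "".join(map(str, h)), "(known)" if known else "")

x = initialize_frequencies(lmap)
print("no-match starting frequencies:", x.tolist(),
      f"-> {x.sum()} separate individuals")
print("null-space basis vectors (merge moves):")
for b in lmap.basis:
    print("   ", b.tolist())
print("each basis vector merges one type-1 and one type-2 record into a")
print("single latent individual while leaving every observed count intact")
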