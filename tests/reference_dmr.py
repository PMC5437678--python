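"""A deliberately naive, loop-based hypo-DMR caller used as the reference
implementation in equivalence tests.

It shares no code with gbmscape.dmr: tiles are found by linear scan,
Fisher p-values come from exact integer enumeration (tests/oracles.py),
the BH adjustment is the O(m^2) textbook definition, and selection/merging
are plain Python loops.
"""

from oracles import bh_adjust_naive, fisher_two_sided_exact


def naive_call_dmrs(wt_df, kd_dfs, chrom_sizes, context, params):
    """Return a list of dicts (chrom, start, end, n_tiles, delta, min_q)."""
    tiles = []
    for chrom, size in chrom_sizes.items():
        s = 0
        while s < size:
            tiles.append((chrom, s, min(s + params.tile_size, size)))
            s += params.tile_size

    def tile_counts(df):
        per = [[0, 0] for _ in tiles]
        for row in df.itertuples(index=False):
            if row.context != context:
                continue
            p0 = row.pos - 1
            for i, (chrom, s, e) in enumerate(tiles):  # linear scan on purpose
                if chrom == row.chrom and s <= p0 < e:
                    per[i][0] += row.n_meth
                    per[i][1] += row.n_unmeth
                    break
        return per

    wt = tile_counts(wt_df)
    kds = [tile_counts(df) for df in kd_dfs]

    per_rep = []
    for kd in kds:
        ps, deltas = [], []
        for (wm, wu), (km, ku) in zip(wt, kd):
            if wm + wu >= params.min_calls and km + ku >= params.min_calls:
                ps.append(float(fisher_two_sided_exact(wm, wu, km, ku)))
            else:
                ps.append(None)
            if wm + wu > 0 and km + ku > 0:
                deltas.append(wm / (wm + wu) - km / (km + ku))
            else:
                deltas.append(None)
        qs = bh_adjust_naive(ps)
        per_rep.append((ps, qs, deltas))

    selected = []
    for i in range(len(tiles)):
        ok = True
        for ps, qs, deltas in per_rep:
            if ps[i] is None or qs[i] is None or deltas[i] is None:
                ok = False
                break
            if not (qs[i] < params.fdr and deltas[i] >= params.min_delta):
                ok = False
                break
        if ok:
            selected.append(i)

    merged = []
    for i in selected:
        chrom, s, e = tiles[i]
        if merged and merged[-1]["chrom"] == chrom and s - merged[-1]["end"] <= params.merge_gap:
            merged[-1]["end"] = max(merged[-1]["end"], e)
            merged[-1]["members"].append(i)
        else:
            merged.append({"chrom": chrom, "start": s, "end": e, "members": [i]})

    def span_counts(df, chrom, start, end):
        m = u = 0
        for row in df.itertuples(index=False):
            if row.context != context or row.chrom != chrom:
                continue
            if start <= row.pos - 1 < end:
                m += row.n_meth
                u += row.n_unmeth
        return m, u

    out = []
    for region in merged:
        chrom, start, end = region["chrom"], region["start"], region["end"]
        wm, wu = span_counts(wt_df, chrom, start, end)
        km = ku = 0
        for df in kd_dfs:
            a, b = span_counts(df, chrom, start, end)
            km += a
            ku += b
        delta = wm / (wm + wu) - km / (km + ku)
        min_q = min(qs[i] for (_, qs, _) in per_rep for i in region["members"])
        out.append({
            "chrom": chrom, "start": start, "end": end,
            "n_tiles": len(region["members"]), "delta": delta, "min_q": min_q,
        })
    return out
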