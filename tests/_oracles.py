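"""Independent brute-force oracles used to cross-check the package.

Everything here is written as direct set comprehensions / full enumeration,
deliberately sharing no code with the implementation under test.
"""

import math
import statistics
from itertools import combinations

from nsafpipe.filter_ladder import OccupancyRule


def _need(k, rule):
    return k if rule is OccupancyRule.ALL else math.ceil(2 * k / 3)


def oracle_ladder(study, rules):
    """Brute-force recomputation of all six ladder stages per dataset."""
    out = {}
    for d in sorted(study.design.datasets):
        runs = [r for k, r in sorted(study.runs.items()) if k.dataset == d]
        total = {p.accession for r in runs for p in r.proteins}
        placenta = {
            a for a in total
            if study.annotation.placenta.get(a, False)
            and a not in study.contaminants.extra_exclusions
            and study.contaminants.frequencies.get(a, 0.0) < rules.contaminant_freq_cutoff
        }

        def seqs(run, acc, smin):
            return {p.sequence for p in run.peptides
                    if acc in p.protein_accessions and p.score >= smin}

        succ = {a for a in placenta
                if any(len(seqs(r, a, rules.min_score)) >= rules.min_peptides
                       for r in runs)}

        samples = sorted({r.key.sample for r in runs})
        rep_rule = rules.replicate_rule_for(d)

        def sample_ok(a, s):
            sruns = [r for r in runs if r.key.sample == s]
            hits = sum(len(seqs(r, a, 0.0)) >= rules.min_peptides for r in sruns)
            return hits >= _need(len(sruns), rep_rule)

        prot = {a for a in succ if any(sample_ok(a, s) for s in samples)}
        need_samples = _need(len(samples), rules.sample_rule_for(d))
        reli = {a for a in prot
                if sum(sample_ok(a, s) for s in samples) >= need_samples}

        def nsaf_values(a):
            vals = []
            for r in runs:
                saf = {p.accession: p.spectral_count / p.length for p in r.proteins}
                v = saf.get(a, 0.0) / sum(saf.values())
                if v > 0:
                    vals.append(v)
            return vals

        quant = set()
        for a in reli:
            vals = nsaf_values(a)
            if len(vals) < 2:
                continue
            m = sum(vals) / len(vals)
            if statistics.stdev(vals) / m <= rules.cv_max or max(vals) / min(vals) <= rules.fc_max:
                quant.add(a)

        out[d] = {"P_total": total, "P_placenta": placenta, "I_successful": succ,
                  "I_proteins": prot, "I_reliably": reli, "Q_reliably": quant}
    return out


def oracle_ranksum(group_a, group_b):
    """Exact two-sided Mann-Whitney test by full enumeration of all
    C(n1+n2, n1) group assignments, with U defined by pairwise comparison
    counts (no ranks involved)."""
    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    pooled = list(group_a) + list(group_b)
    n1 = len(group_a)
    obs = u_stat(group_a, group_b)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        us.append(u_stat(xs, ys))
    p_low = sum(u <= obs + 1e-9 for u in us) / len(us)
    p_high = sum(u >= obs - 1e-9 for u in us) / len(us)
    return obs, min(1.0, 2.0 * min(p_low, p_high))
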