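"""Independent brute-force oracles, written with explicit loops and no code
shared with the package, for cross-checking weight derivation and the
log-rank test on tiny fixtures."""

import math


def brute_force_weights(mutations, panel, mode="ols_intercept"):
    """Weight derivation by longhand enumeration.

    ``mutations``: dict sample_id -> list of gene symbols (one entry per
    mutation; the sample's load is the list length).  Returns a dict with
    slope, unadjusted, adjusted, excluded.
    """
    atml = {s: len(genes) for s, genes in mutations.items()}

    unadjusted = {}
    excluded = set()
    for gene in panel:
        carrier_loads = []
        for s, genes in mutations.items():
            if gene in genes:
                carrier_loads.append(atml[s])
        if carrier_loads:
            lowest = carrier_loads[0]
            for v in carrier_loads[1:]:
                if v < lowest:
                    lowest = v
            unadjusted[gene] = lowest
        else:
            excluded.add(gene)

    xs, ys = [], []
    for s in sorted(mutations):
        total = 0
        for gene in panel:
            if gene in unadjusted:
                count = 0
                for g in mutations[s]:
                    if g == gene:
                        count += 1
                total += unadjusted[gene] * count
        xs.append(atml[s])
        ys.append(total)

    n = len(xs)
    if mode == "ols_intercept":
        xbar = sum(xs) / n
        ybar = sum(ys) / n
        sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
        sxx = sum((x - xbar) ** 2 for x in xs)
        slope = sxy / sxx
    else:
        slope = sum(x * y for x, y in zip(xs, ys)) / sum(x * x for x in xs)

    adjusted = {}
    for gene, value in unadjusted.items():
        adjusted[gene] = int(math.floor(value / slope + 0.5))
    return {
        "slope": slope,
        "unadjusted": unadjusted,
        "adjusted": adjusted,
        "excluded": excluded,
    }


def brute_force_logrank(times, events, groups):
    """Unweighted two-group log-rank statistic by longhand risk-set walks.

    Returns (chi_square, p_value); p via the 1-df chi-square survival
    function expressed with erfc, so no statistics library is involved.
    """
    labels = sorted(set(groups))
    assert len(labels) == 2
    event_times = sorted({t for t, e in zip(times, events) if e == 1})

    observed1 = 0.0
    expected1 = 0.0
    variance = 0.0
    for tj in event_times:
        n_total = 0
        n_group1 = 0
        d_total = 0
        d_group1 = 0
        for t, e, g in zip(times, events, groups):
            if t >= tj:
                n_total += 1
                if g == labels[0]:
                    n_group1 += 1
            if e == 1 and t == tj:
                d_total += 1
                if g == labels[0]:
                    d_group1 += 1
        observed1 += d_group1
        expected1 += d_total * n_group1 / n_total
        if n_total > 1:
            variance += (
                d_total
                * (n_group1 / n_total)
                * (1 - n_group1 / n_total)
                * (n_total - d_total)
                / (n_total - 1)
            )
    chi_square = (observed1 - expected1) ** 2 / variance
    p_value = math.erfc(math.sqrt(chi_square / 2.0))
    return chi_square, p_value


def brute_force_km(times, events):
    """Product-limit curve at distinct event times, by longhand loops."""
    event_times = sorted({t for t, e in zip(times, events) if e == 1})
    surv = 1.0
    curve = []
    for tj in event_times:
        at_risk = sum(1 for t in times if t >= tj)
        d = sum(1 for t, e in zip(times, events) if e == 1 and t == tj)
        surv *= 1.0 - d / at_risk
        curve.append((tj, surv, at_risk, d))
    return curve
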