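"""Independent brute-force oracles shared across test modules."""


def chain_enumeration(n_days, dl, ml, dp, mp, ei=0.0):
    """Exact expected state occupancy of the two-stage daily competing-risk
    chain, mirroring the simulator's update order (new pupae enter risk the
    following day).  Pure recursion on expectations — independent of the
    sampling code it checks."""
    p_larva, p_pupa = 1.0, 0.0
    dead_l = dead_p = emerged = blocked = 0.0
    for _ in range(n_days):
        new_dead_l = p_larva * dl
        new_molt = p_larva * ml
        p_larva -= new_dead_l + new_molt
        dead_l += new_dead_l
        new_dead_p = p_pupa * dp
        attempted = p_pupa * mp
        emerged += attempted * (1 - ei)
        blocked += attempted * ei
        dead_p += new_dead_p
        p_pupa = p_pupa - new_dead_p - attempted + new_molt
    return {"dead_l": dead_l, "dead_p": dead_p + blocked, "emerged": emerged,
            "censored": p_larva + p_pupa}
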