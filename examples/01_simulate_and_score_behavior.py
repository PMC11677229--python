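"""Simulate a conditioned cohort and quantify lick behavior per session.

Builds a 5-session cohort, scores every trial into hit/miss/FA/CR from the
lick times, and prints per-session response probabilities with exact
binomial confidence intervals. Discrimination = P(lick|CS+) − P(lick|CS−)
should rise across rewarded sessions and collapse during the unrewarded
post session as licking extinguishes.
"""
import tuftpipe as tp

cfg = tp.SimConfig(n_tufts=5, n_sessions=5, n_trials=180, seed=1)
sessions, gt = tp.simulate_cohort(cfg)

print(f"{'session':>16} {'P(lick|CS+)':>12} {'P(lick|CS-)':>12} {'discrim':>8}")
for s in sessions:
    beh = tp.session_behavior_summary(s.trials, s.licks)
    print(f"{s.session_label:>16} "
          f"{beh.p_lick_csp:6.2f} [{beh.ci_csp[0]:.2f},{beh.ci_csp[1]:.2f}] "
          f"{beh.p_lick_csm:6.2f} [{beh.ci_csm[0]:.2f},{beh.ci_csm[1]:.2f}] "
          f"{beh.discrimination:8.2f}")

post = sessions[-1]
blocks, _ = tp.extinction_blocks(post.trials, post.licks)
print("\npost-session CS+ lick probability per 20-trial block "
      "(extinction):", [round(float(b), 2) for b in blocks])
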