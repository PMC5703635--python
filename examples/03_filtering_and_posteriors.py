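"""Filter one locus trajectory and smooth its latent frequency.

The HMM treats the population allele frequency as a latent state observed
through binomial read sampling.  The forward pass yields the marginal
likelihood; the forward-backward pass yields the posterior frequency
distribution at each sampling instant given all the data.
"""

from drifthmm import AlleleTrajectory, DriftModelSpec, forward_backward, forward_filter

# a locus rising from ~10% to ~45% over 59 generations, uneven depths
traj = AlleleTrajectory(
    "2L:5002",
    times=(0, 15, 37, 59),
    n=(11, 19, 30, 44),
    C=(100, 90, 105, 98),
)
model = DriftModelSpec("WF", theta=400)

res = forward_filter(traj, model)
posts = forward_backward(traj, model)

print(f"log likelihood under WF(N=400): {res.log_likelihood:.3f}")
for t, post in zip(traj.times, posts):
    lo, hi = post.mean() - 2 * post.variance() ** 0.5, post.mean() + 2 * post.variance() ** 0.5
    print(f"  t={t:3d}: posterior mean q = {post.mean():.3f}  (~95% band {lo:.3f}-{hi:.3f})")
# the smoothed means shrink the raw read fractions toward trajectories that
# are plausible under N=400 drift.
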