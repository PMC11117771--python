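# ACAN behaviour presets, one row per cortical firing pattern.
#
# Each entry fixes the five vector-field shape coefficients (gamma), the
# recovery gain mu and the two reset fractions (rho1, rho2).  The speed
# divisor lambda is set equal to the register size R when a preset is
# instantiated, and all four registers are uniform (N = M = K = J = R).
#
# Pattern taxonomy: a tonic spiking, b phasic spiking, c tonic bursting,
# d phasic bursting, e mixed-mode spiking, f spike frequency adaptation,
# g class 1 excitation, h class 2 excitation, i spike latency,
# j sub-threshold oscillation, k resonator, l integrator, m rebound spike,
# n rebound burst, o threshold variability, p bistability,
# q depolarizing after-potential, r accommodation,
# s inhibition-induced spiking, t inhibition-induced bursting.
a: {gamma: [7, 0.3, 0.2, 2.8, 0.06], mu: 0.7, rho1: 0.3, rho2: 0.0}
b: {gamma: [7, 0.3, 0.2, 2.8, 0.06], mu: 0.7, rho1: 0.3, rho2: 0.0}
c: {gamma: [7, 0.3, 0.2, 2.8, 0.06], mu: 0.7, rho1: 0.55, rho2: -0.2}
d: {gamma: [7, 0.3, 0.2, 2.8, 0.06], mu: 0.7, rho1: 0.55, rho2: -0.2}
e: {gamma: [7, 0.3, 0.2, 2.8, 0.06], mu: 0.7, rho1: 0.55, rho2: -0.2}
f: {gamma: [7, 0.3, 0.2, 1.1, 0.03], mu: 0.01, rho1: 0.2, rho2: 0.15}
g: {gamma: [7, 0.3, 0.2, -0.5, 0.05], mu: 4.0, rho1: 0.25, rho2: 0.4}
h: {gamma: [7, 0.3, 0.2, 3.0, -0.09], mu: 0.5, rho1: 0.3, rho2: 0.0}
i: {gamma: [7, 0.3, 0.2, -0.5, 0.05], mu: 4.0, rho1: 0.25, rho2: 0.4}
j: {gamma: [7, 0.3, 0.2, 3.0, -0.09], mu: 0.5, rho1: 0.3, rho2: 0.0}
k: {gamma: [7, 0.3, 0.2, 3.0, -0.09], mu: 0.5, rho1: 0.3, rho2: 0.0}
l: {gamma: [7, 0.3, 0.2, -0.5, 0.05], mu: 4.0, rho1: 0.25, rho2: 0.4}
m: {gamma: [7, 0.3, 0.2, 3.0, -0.1], mu: 0.5, rho1: 0.3, rho2: 0.0}
n: {gamma: [7, 0.3, 0.2, 3.0, -0.1], mu: 0.5, rho1: 0.48, rho2: -0.42}
o: {gamma: [7, 0.3, 0.2, 3.0, 0.1], mu: 0.5, rho1: 0.3, rho2: 0.0}
p: {gamma: [7, 0.3, 0.2, 3.0, -0.11], mu: 0.5, rho1: 0.3, rho2: 0.0}
q: {gamma: [7, 0.3, 0.2, -0.5, 0.15], mu: 0.5, rho1: 0.2, rho2: -0.3}
r: {gamma: [7, 0.3, 0.2, 2.8, 0.06], mu: 0.7, rho1: 0.3, rho2: 0.0}
s: {gamma: [7, 0.3, 0.5, -5.0, 0.0], mu: -0.1, rho1: 0.4, rho2: 0.3}
t: {gamma: [7, 0.3, 0.5, -5.0, 0.0], mu: -0.1, rho1: 0.55, rho2: -0.1}
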