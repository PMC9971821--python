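# Baseline parameterisation of the DPHP/MPHP PBPK model.
#
# Keys follow the abbreviations used in the physiological parameter table of
# the model description.  Volume and flow entries are percentages (of body
# weight and of cardiac output respectively), protein binding is a
# percentage; the loader converts them to fractions.  Entries marked
# "plumbing" are model-structure constants that do not come from the
# physiological tables; they are exposed here so they can be varied.

# --- anatomy / physiology ---
BW: 72.3            # body weight, kg
VT: 0.95            # total vascularised fraction of BW
VLiC: 3.09          # liver, % BW
VKiC: 0.58          # kidney, % BW
VFaC: 19.5          # fat, % BW
VGuC: 1.50          # gut, % BW
VStC: 0.22          # stomach, % BW
VSpdC: 60.7         # slowly perfused, % BW
VRpdC: 3.71         # rapidly perfused, % BW
VBldC: 5.0          # blood, % BW
QCC: 14.0           # cardiac output coefficient, L h^-1 kg^-0.75
QHepartC: 6.9       # hepatic artery, % cardiac output
QKiC: 20.0          # kidney, % cardiac output
QFaC: 5.0           # fat, % cardiac output
QGuC: 14.9          # gut, % cardiac output
QStC: 1.1           # stomach, % cardiac output
QSpdC: 28.7         # slowly perfused, % cardiac output
QRpdC: 23.0         # rapidly perfused, % cardiac output
allometric_exponent: 0.75   # cardiac-output BW scaling exponent (plumbing)

# --- binding (percent bound in arterial blood) ---
FB_DPHP: 99.75
FB_MPHP: 98.54

# --- metabolism ---
T_half_DPHP: 3.0        # in-vitro hepatic half-life, min
T_half_MPHP: 8.05       # in-vitro hepatic half-life, min
T_half_DPHP_gut: 60.0   # in-vivo gut half-life, min
MPY: 34.0               # hepatic microsomal protein yield, mg g^-1
MPYgu: 3.9              # gut microsomal protein yield, mg g^-1
incubation_protein_conc: 1.0   # in-vitro incubation protein, mg mL^-1 (plumbing)

# --- tissue:blood partition coefficients ---
LogPow_DPHP: 10.83
LogPow_MPHP: 5.3
Pbab: 15.5      # plasma, DPHP
Pfab: 63.4      # adipose, DPHP
Plib: 5.89      # liver, DPHP
Pkib: 5.89      # kidney, DPHP
Pmub: 3.29      # muscle, DPHP
Prbb: 3.01      # red blood cells, DPHP
Pgub: 7.4       # gut, DPHP
Pspb: 3.7       # spleen, DPHP
Pstb: 7.4       # stomach (gut surrogate), DPHP
Prpdb: 3.7      # rapidly perfused (spleen surrogate), DPHP
Pspdb: 3.29     # slowly perfused (muscle surrogate), DPHP
PbaM: 25.23     # plasma, MPHP
PfaM: 29.10     # adipose, MPHP
PliM: 54.8      # liver, MPHP
PkiM: 15.5      # kidney, MPHP
PmuM: 7.51      # muscle, MPHP
PrbM: 6.67      # red blood cells, MPHP
PguM: 25.2      # gut, MPHP
PspM: 12.20     # spleen, MPHP
PstM: 25.2      # stomach (gut surrogate), MPHP
PrpdM: 12.20    # rapidly perfused (spleen surrogate), MPHP
PspdM: 7.51     # slowly perfused (muscle surrogate), MPHP

# --- uptake / transport ---
FracDOSEHep: 0.202      # fraction of oral dose absorbable via the gut route
FracDoseLymph: 0.075    # fraction of oral dose taken up via lymphatics
BELLYPERM: 3.72         # stomach -> venous blood uptake, h^-1
GIPERM1: 4.98           # gut section 1 -> portal uptake, h^-1
GIPERM2: 15.17          # gut section 2 -> portal uptake, h^-1
Gutlag: 2.51            # delay before gut1 -> gut2 transit, h
k_transit: 1.0          # gut1 -> gut2 transit rate after Gutlag, h^-1 (plumbing)
k_st_gut: 2.0           # gastric emptying, h^-1 (plumbing)
Lymphlag: 3.50          # delay before lymphatic release, h
K1_Lymph: 1.53          # lymph -> venous blood rate, h^-1
K1_DPHP_Liver: 10.0     # liver -> bile first-order rate, h^-1
bile_delay: 1.0         # mean bile-transit residence, h (plumbing)
k_abs_MPHP_gut: 2.0     # absorption of gut-formed MPHP, h^-1 (plumbing)

# --- metabolite routing / elimination ---
Escape_gu: 0.5          # gut-absorbed MPHP entering venous blood bound
Escape_Li: 0.5          # liver-formed MPHP escaping immediate metabolism
FracMetab_MOH: 0.35     # metabolised MPHP appearing as OH-MPHP
FracMetab_cx: 0.03      # metabolised MPHP appearing as cx-MPHP
K1_MPHP: 2.52           # kidney -> urine, h^-1
K1_MOH: 2.52            # OH-MPHP blood pool -> urine, h^-1
K1_cx: 2.52             # cx-MPHP blood pool -> urine, h^-1

# --- molecular masses, g mol^-1 (from molecular formulas; plumbing) ---
MW_DPHP: 446.67         # C28H46O4
MW_MPHP: 306.40         # C18H26O4
MW_OH_MPHP: 322.40      # C18H26O5
MW_cx_MPHP: 336.38      # C18H24O6

# --- numerics ---
hs_width: 0.01          # Heaviside smoothing width for lag switches, h
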