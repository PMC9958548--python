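>synthetic_knottin_6.0_1
LCINCAGCCARCPTCMN
>synthetic_knottin_6.0_2
TCWSCEYCCHSCATTLDMPACKP
>synthetic_knottin_6.0_3
PCMDCHHRCCLTIIWIEHCFKYMVCRR
>synthetic_knottin_8.0_1
PCQNKVIVVKCIMVYSVCCHMQNAINCWCEHCDCKS
>synthetic_knottin_8.0_2
SCSDCISAYGCCFPKFCPCGDVYSMPCICWN
>synthetic_knottin_8.0_3
TCIEWCNRQQDVHCCNFYYQCTCEVQRCYCNW
>synthetic_knottin_10.0_1
NCSIHQYCHERCLCCGQHCFCDSWFCACWVWTACQN
>synthetic_knottin_10.0_2
VCIESGNACGRMQCFCCGNGMKKRMCDCVYCMCFFCFD
>synthetic_knottin_10.0_3
HCQNECRPCMCCEFHVKCDCHFNGCICGDCTQ
>synthetic_knottin_10.1_1
WCVGNINILICIMTKCCCQWCTCSYNTTQNICHCVACTD
>synthetic_knottin_10.1_2
YCYIATRHYCMEVDAVWHCCCWKPSCFCKKCICFKTCRT
>synthetic_knottin_10.1_3
VCFQVYWCKFCCCMKHYQAGCLCTLDYHCQCHIQFSYTCVH
>synthetic_knottin_12.0_1
HCEPPNECTVFFCRCCLEDCMCGYKSVWCNCSDVTGHACTEFLPMVVCSGKVCRW
>synthetic_knottin_12.0_2
KCLWECWHRVCWCCMDGCLCVWQQECHCIRCRYCPATCDD
>synthetic_knottin_12.0_3
MCMYADCMFCNCCDAKCHCDAVCMCESFSTYCNLSRCATYWCHI
>synthetic_knottin_12.1_1
HCHTMRVGCSMRPTCNCCPCEHHFLLMKCWCEYWISNCPCSKVFMACQTPGVPACMM
>synthetic_knottin_12.1_2
LCQTVDHVECQHTGKGCPCCTCLNGCGCWIAHCWCEPMNVHCLTCYN
>synthetic_knottin_12.1_3
YCHPLQGEPGCWSKILPGCKCCQCAEVLSDVCRCEHRYCVCDGSFMCFFPCRY
>synthetic_knottin_14.0_1
HCPKDTRACRHICMCCLWAMPHGKCECIFRKLKLCHCDAKQFPPCWNWCRSIFCDGRDHCIDTVLLIACSI
>synthetic_knottin_14.0_2
LCYIGMWGNCFADMERCICCTRCVCIPLMKVCRCAVGACTDTMWCLATWYIKCMNESYCQTHVLQYTCML
>synthetic_knottin_14.0_3
ECWECQTHCGCCQDCDCPHIEYCGCHSLIVAHMCHTQGITFCVKSRPCFETYDCDRCMN
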