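>petrobactin_synthetase
EMDYDMNPASVINDDKHAFEELYCWFNAYYWLDMMSHDGKNQARPSCACKYYFYMCHNPK
LFTIEPLNCMVYDNDNNLPRRQHFDQMHAHEFANDYCMNMVFPKAFIRRIGLYMANIETN
TLFKAILRKNATHAEWELIDEYTYRMGQCNETKLQPEHGYVTQRWRRLWISIQIEEKVYV
CCNKDTNQGVVNWLWSKAESHFSWAGISKSACECSPSHIHDEDRWKKQKMRQRPKYANHV
WAGFAHEQQWQSLSADDSMFLQMGMRPTELKVYDQESEMWYMQHYHHWKIYDDGANILCH
>vibrioferrin_synthetase
YWGTFVIWTAGWFMIIMVEWCWSGEAKELFYSSPTFKPKQQRCKYASKVDHVFVHFHQDG
NRYNWWGDTQYCNAADIMDLPQLFIVGILDFIAIGQVCQTYGADWAYEWIGVIFGTAVCH
CQVLAEQWEQLWMGTNYHYHNFQEEDQHVTAPVLSTGPNEVHGQSQGHETHCKLLILYFD
FSCVVLERTNATHMIVNFDRMGGVKQEMEPIMKWAPIVSQTWELRPVVRYGSKLSLWNRW
WFNNDPYKFAQIMNESHDQDFDVDPSSAMSMFLMRLATKYQQCMEPMGPGTPCCMCNKEA
>rhizoferrin_synthetase
FNVLCWHWGQKIVKTCMARSSGYHMQSGWPDMKIQETYNHIHLSHHQDFDDLATTGQAPW
QSIQPRDSKHESINKMYFTINVMRWIPLYTLLSKHCQETYDDWNCWTYMDRCTIYCNYKY
MHYLYQYCMLPSGMYHWIHAWDYTNPDRHPVIYVVCNKETRYCMWEGKLWTHKGTMAPRG
DKQNRRDDIYKNDLDPARCDCALWKSSWFSRCTGVQFYWWHYNGLDTMQLHWRCPISCCK
NHADRDDAPSKWSFHPVLQQYEKKVHPRTHMRFFMMKEHNRTEAYRRSIHTARVKSAIAM
>aerobactin_synthetase
EVGCDITAPMDKFHDFVKKIVNFRCMIVLFWNMNGWVKRVKDAGNIWAIYYYGNEAPFIA
NLMEIHCNNPINKNHHARKKDVEIRDCNKRQPDYYDPLQMHVYWQLHIEMDDWCIYMMVA
VSQLIVWFPCAMCCTHLTTMQDGMANQMEICSRQYFMTQKFPCATNHRKWMRVAQRCIVY
AQDMSNYCQNVSHMWYGEKFWPRGHFYQLGPWIHLGSLEDQCKAGHYFNNTVDIYPDHGN
TMCQILLPHRGKIIPGNMPQNQGVEDNNDWGIDGKAWCMNVQVIQQLFFMFFETWKEVHK
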