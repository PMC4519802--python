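PATH_0	synthetic pathway	GENE000	GENE005	GENE006	GENE008	GENE012	GENE013	GENE020	GENE026	GENE043	GENE045	GENE051	GENE052	GENE061	GENE063	GENE065	GENE066	GENE068	GENE074	GENE077	GENE078	GENE079	GENE081	GENE087	GENE088	GENE090	GENE092	GENE098
PATH_1	synthetic pathway	GENE001	GENE004	GENE005	GENE007	GENE009	GENE012	GENE015	GENE017	GENE021	GENE029	GENE043	GENE044	GENE045	GENE046	GENE047	GENE051	GENE053	GENE059	GENE061	GENE065	GENE067	GENE072	GENE076	GENE082	GENE085	GENE089	GENE092	GENE094
PATH_2	synthetic pathway	GENE000	GENE004	GENE005	GENE007	GENE013	GENE020	GENE026	GENE037	GENE038	GENE039	GENE048	GENE053	GENE061	GENE062	GENE072	GENE086	GENE091	GENE092	GENE099
PATH_3	synthetic pathway	GENE003	GENE005	GENE007	GENE024	GENE031	GENE033	GENE039	GENE050	GENE051	GENE058	GENE062	GENE063	GENE069	GENE072	GENE074	GENE089	GENE096	GENE098	GENE099
PATH_4	synthetic pathway	GENE002	GENE007	GENE021	GENE026	GENE033	GENE036	GENE039	GENE044	GENE050	GENE057	GENE068	GENE069	GENE071	GENE072	GENE075	GENE094	GENE095
PATH_5	synthetic pathway	GENE026	GENE038	GENE046	GENE050	GENE059	GENE067	GENE070	GENE093
PATH_6	synthetic pathway	GENE000	GENE001	GENE014	GENE018	GENE021	GENE029	GENE035	GENE036	GENE040	GENE043	GENE045	GENE051	GENE054	GENE056	GENE057	GENE067	GENE068	GENE075	GENE076	GENE077	GENE081	GENE084	GENE085	GENE090	GENE093	GENE097	GENE099
PATH_7	synthetic pathway	GENE002	GENE004	GENE011	GENE012	GENE025	GENE026	GENE047	GENE049	GENE053	GENE079	GENE084	GENE085	GENE088	GENE092
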