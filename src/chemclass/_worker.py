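"""Child-process worker that loads and runs one candidate classifier program.

Run as a standalone script (no package imports, so startup stays cheap for
programs that never touch the chemistry toolkit).  Protocol: a single JSON
request on stdin::

    {"source": ..., "function_name": ..., "smiles": [...],
     "timeout_s": 10.0, "check_only": false}

and a single JSON line on stdout — either ``{"fatal": "<captured error>"}``
or ``{"results": [["ok", m, e] | ["error", null, "<message>"], ...]}``.

Containment: the candidate source is exec'd with a restricted builtins dict
(no open/exec/eval; print routed to stderr) whose ``__import__`` enforces an
allowlist of chemistry, math and string modules and denies network/process
modules.  Each classification call is wall-clock capped with SIGALRM.  This
contains accidental faults in generated code; it is not a hostile-code
security boundary.
"""

import builtins
import json
import signal
import sys
import traceback

ALLOWED_ROOTS = {
    "rdkit", "numpy", "math", "cmath", "re", "itertools", "collections",
    "functools", "operator", "string", "statistics", "fractions", "decimal",
    "heapq", "bisect", "random", "typing", "dataclasses", "enum", "copy",
    "abc", "array", "numbers", "unicodedata", "textwrap", "warnings",
}
DENIED_ROOTS = {
    "socket", "ssl", "http", "urllib", "ftplib", "smtplib", "poplib",
    "imaplib", "telnetlib", "xmlrpc", "requests", "subprocess", "os",
    "multiprocessing", "ctypes", "shutil", "pathlib", "importlib", "sys",
}
REMOVED_BUILTINS = {"open", "exec", "eval", "compile", "input", "breakpoint",
                    "exit", "quit", "help", "memoryview", "vars", "globals"}


class CallTimeout(Exception):
    pass


def _guarded_import(name, globals=None, locals=None, fromlist=(), level=0):
    root = name.split(".")[0]
    if root in DENIED_ROOTS:
        raise ImportError(f"import of {name!r} is not permitted in classifier programs")
    if root not in ALLOWED_ROOTS:
        raise ImportError(
            f"import of {name!r} is not in the classifier-program allowlist"
        )
    return _real_import(name, globals, locals, fromlist, level)


_real_import = builtins.__import__


def _safe_builtins():
    safe = {k: v for k, v in vars(builtins).items() if k not in REMOVED_BUILTINS}
    safe["__import__"] = _guarded_import
    safe["print"] = lambda *a, **k: print(*a, file=sys.stderr)
    return safe


def _alarm(signum, frame):
    raise CallTimeout()


def main() -> None:
    request = json.loads(sys.stdin.read())
    source = request["source"]
    function_name = request["function_name"]
    out = sys.stdout

    if "rdkit" in source:
        # Pre-load the toolkit under unrestricted builtins; candidate imports
        # then resolve against the warm sys.modules cache.
        try:
            from rdkit import Chem, RDLogger  # noqa: F401

            RDLogger.DisableLog("rdApp.*")
        except Exception:
            pass

    program_globals = {"__name__": "candidate_program", "__builtins__": _safe_builtins()}
    try:
        code = compile(source, "<candidate>", "exec")
        exec(code, program_globals)
    except BaseException:
        json.dump({"fatal": traceback.format_exc(limit=5)}, out)
        out.write("\n")
        return
    fn = program_globals.get(function_name)
    if not callable(fn):
        json.dump(
            {"fatal": f"program does not define a callable named {function_name!r}"},
            out,
        )
        out.write("\n")
        return
    if request.get("check_only"):
        json.dump({"results": []}, out)
        out.write("\n")
        return

    timeout_s = float(request.get("timeout_s", 10.0))
    signal.signal(signal.SIGALRM, _alarm)
    results = []
    for smiles in request["smiles"]:
        try:
            signal.setitimer(signal.ITIMER_REAL, timeout_s)
            try:
                value = fn(smiles)
            finally:
                signal.setitimer(signal.ITIMER_REAL, 0)
            if (
                not isinstance(value, tuple)
                or len(value) != 2
                or not isinstance(value[0], bool)
            ):
                results.append(
                    ["error", None, f"malformed return value: {value!r}"]
                )
                continue
            m, e = value
            e = str(e) if e else ("classified as member" if m else "classified as non-member")
            results.append(["ok", m, e])
        except CallTimeout:
            results.append(["error", None, f"timeout after {timeout_s} s"])
        except BaseException as exc:  # noqa: BLE001 - containment is the contract
            results.append(["error", None, f"{type(exc).__name__}: {exc}"])
    json.dump({"results": results}, out)
    out.write("\n")


if __name__ == "__main__":
    main()
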